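"""Representative-patch selection at the tumor-parenchyma interface.

Given a whole-slide prediction map (a grid of tissue-class labels per patch
position), this module finds the largest connected PanNET component (the
tumor region of interest, TRoI), marks its border patches -- TRoI cells
adjacent to a patch labeled NNPP or stroma (adjacency to background alone
does not qualify) -- and expands the selection breadth-first into the tumor
up to a maximum hop distance. Each selected patch carries its hop distance
d: the shortest within-TRoI path length to any border patch (d=0 on the
border). Hop distances weight the patches' contributions to the scoring
loss downstream.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import ndimage

from .labels import NNPP, PANNET, STROMA

__all__ = [
    "TumorRegion",
    "SelectedPatch",
    "find_largest_troi",
    "select_border",
    "expand_hops",
    "select_representative_patches",
    "write_selection_csv",
    "read_selection_csv",
    "selection_summary",
]

_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class TumorRegion:
    """Largest connected PanNET component of a prediction map."""

    cells: frozenset  # of (row, col)
    component_id: int
    connectivity: int

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass(frozen=True, order=True)
class SelectedPatch:
    """A selected TRoI patch with its hop distance from the interface."""

    row: int
    col: int
    hop_distance: int
    slide_id: str = ""


def find_largest_troi(grid: np.ndarray, connectivity: int = 4) -> TumorRegion:
    """Return the PanNET connected component with the most cells.

    Ties are broken deterministically in favor of the component whose
    minimal (row, col) member is smallest. Raises ``ValueError`` when the
    map contains no PanNET cell.
    """
    grid = np.asarray(grid)
    mask = grid == PANNET
    if not mask.any():
        raise ValueError("no tumor found: prediction map has no PanNET cells")
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    best = int(np.max(sizes))
    candidates = [i + 1 for i, s in enumerate(sizes) if int(s) == best]
    if len(candidates) > 1:
        # smallest minimal member in row-major order wins
        def min_member(cid: int) -> Tuple[int, int]:
            rows, cols = np.nonzero(lab == cid)
            order = np.lexsort((cols, rows))
            return int(rows[order[0]]), int(cols[order[0]])
        candidates.sort(key=min_member)
    cid = candidates[0]
    rows, cols = np.nonzero(lab == cid)
    cells = frozenset((int(r), int(c)) for r, c in zip(rows, cols))
    return TumorRegion(cells=cells, component_id=cid, connectivity=connectivity)


def select_border(
    troi: TumorRegion, grid: np.ndarray, slide_id: str = ""
) -> Set[SelectedPatch]:
    """Border patches of the TRoI (hop distance 0).

    A TRoI cell qualifies iff at least one neighbor (under the region's
    connectivity) is labeled NNPP or stroma; background neighbors alone do
    not make a cell a border cell.
    """
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    offsets = _OFFSETS[troi.connectivity]
    border: Set[SelectedPatch] = set()
    for (r, c) in troi.cells:
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and grid[rr, cc] in (NNPP, STROMA):
                border.add(SelectedPatch(r, c, 0, slide_id))
                break
    if not border:
        warnings.warn("TRoI has no NNPP/stroma neighbors; empty border selection",
                      stacklevel=2)
    return border


def expand_hops(
    border: Set[SelectedPatch],
    troi: TumorRegion,
    max_hops: int,
) -> Set[SelectedPatch]:
    """Breadth-first expansion of the border into the TRoI up to ``max_hops``.

    Each selected patch's hop distance is the shortest within-TRoI path
    length to any border patch; cells farther than ``max_hops`` are dropped.
    """
    if max_hops < 0:
        raise ValueError("max_hops must be >= 0")
    offsets = _OFFSETS[troi.connectivity]
    dist: Dict[Tuple[int, int], int] = {}
    queue: deque = deque()
    slide_id = ""
    for p in border:
        dist[(p.row, p.col)] = 0
        queue.append((p.row, p.col))
        slide_id = p.slide_id
    while queue:
        r, c = queue.popleft()
        d = dist[(r, c)]
        if d >= max_hops:
            continue
        for dr, dc in offsets:
            nxt = (r + dr, c + dc)
            if nxt in troi.cells and nxt not in dist:
                dist[nxt] = d + 1
                queue.append(nxt)
    return {SelectedPatch(r, c, d, slide_id) for (r, c), d in dist.items()}


def select_representative_patches(
    grid: np.ndarray,
    max_hops: int = 6,
    connectivity: int = 4,
    slide_id: str = "",
) -> Set[SelectedPatch]:
    """End-to-end selection: largest TRoI -> border -> hop expansion."""
    troi = find_largest_troi(grid, connectivity)
    border = select_border(troi, grid, slide_id)
    if not border:
        return set()
    return expand_hops(border, troi, max_hops)


def interface_distances(
    grid: np.ndarray, connectivity: int = 4
) -> Dict[Tuple[int, int], int]:
    """Within-TRoI geodesic distance to the interface for every TRoI cell.

    Convenience used by the synthetic-slide generator: an uncapped hop
    expansion returned as a dict keyed by (row, col).
    """
    troi = find_largest_troi(grid, connectivity)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        border = select_border(troi, grid)
    if not border:
        return {}
    selected = expand_hops(border, troi, max_hops=grid.size)
    return {(p.row, p.col): p.hop_distance for p in selected}


def write_selection_csv(patches: Iterable[SelectedPatch], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slide_id", "row", "col", "hop_distance"])
        for p in sorted(patches):
            w.writerow([p.slide_id, p.row, p.col, p.hop_distance])


def read_selection_csv(path) -> List[SelectedPatch]:
    out: List[SelectedPatch] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SelectedPatch(int(row["row"]), int(row["col"]),
                                     int(row["hop_distance"]), row["slide_id"]))
    return out


def selection_summary(patches: Iterable[SelectedPatch],
                      troi: Optional[TumorRegion] = None) -> dict:
    """JSON-serializable summary: TRoI size, border count, per-d counts."""
    patches = list(patches)
    per_d: Dict[int, int] = {}
    for p in patches:
        per_d[p.hop_distance] = per_d.get(p.hop_distance, 0) + 1
    return {
        "troi_size": troi.size if troi is not None else None,
        "n_selected": len(patches),
        "border_count": per_d.get(0, 0),
        "per_hop_counts": {str(d): n for d, n in sorted(per_d.items())},
    }
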