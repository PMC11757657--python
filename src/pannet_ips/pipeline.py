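"""End-to-end orchestration: tissue map -> selected patches -> case bags.

Convenience layer used by the examples, the CLI, and the cross-validation
harness: given a cohort of slides (synthetic or prediction maps plus
nucleus exports), select the representative interface patches of each
slide, build their cell-graphs, and pool each case's graphs into a bag for
training and case-level voting.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Sequence

from .cell_graph import CellGraph, Nucleus, build_cell_graph
from .fixtures import CaseRecord, SyntheticSlide
from .patch_selection import select_representative_patches

__all__ = ["GraphBuildConfig", "build_slide_graphs", "build_case_bags"]


@dataclass
class GraphBuildConfig:
    """Knobs of patch selection and cell-graph construction."""

    max_hops: int = 6
    connectivity: int = 4
    k_neighbors: int = 5
    max_edge_dist: float = 50.0
    similarity_threshold: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def build_slide_graphs(
    slide: SyntheticSlide,
    cfg: Optional[GraphBuildConfig] = None,
    label: Optional[str] = None,
) -> List[CellGraph]:
    """Select interface patches on one slide and build their cell-graphs."""
    cfg = cfg or GraphBuildConfig()
    selected = select_representative_patches(
        slide.tissue_map, max_hops=cfg.max_hops,
        connectivity=cfg.connectivity, slide_id=slide.slide_id)
    graphs: List[CellGraph] = []
    for p in sorted(selected):
        ns = slide.nuclei[(p.row, p.col)]
        nuclei = [Nucleus(centroid=tuple(c), features=f)
                  for c, f in zip(ns.centroids, ns.features)]
        graphs.append(build_cell_graph(
            nuclei, k=cfg.k_neighbors, max_edge_dist=cfg.max_edge_dist,
            similarity_threshold=cfg.similarity_threshold,
            slide_id=slide.slide_id, coords=(p.row, p.col),
            hop_distance=p.hop_distance, label=label))
    return graphs


def build_case_bags(
    cases: Sequence[CaseRecord],
    slides: Sequence[SyntheticSlide],
    cfg: Optional[GraphBuildConfig] = None,
) -> Dict[str, List[CellGraph]]:
    """Pool each case's per-slide graphs into one bag keyed by case id.

    Every graph carries the case's IPS label (weak supervision: the
    case-level label stands in for each selected patch of the case).
    """
    cfg = cfg or GraphBuildConfig()
    by_id: Mapping[str, SyntheticSlide] = {s.slide_id: s for s in slides}
    bags: Dict[str, List[CellGraph]] = {}
    for case in cases:
        bag: List[CellGraph] = []
        for sid in case.slide_ids:
            if sid not in by_id:
                raise ValueError(f"case {case.case_id}: slide {sid} missing")
            bag.extend(build_slide_graphs(by_id[sid], cfg,
                                          label=case.ips_label))
        bags[case.case_id] = bag
    return bags
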