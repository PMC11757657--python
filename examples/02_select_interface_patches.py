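"""Select representative tumor-parenchyma interface patches on one slide.

Finds the largest connected PanNET component in a tissue map, marks its
border patches (those touching NNPP or stroma), and expands breadth-first
into the tumor up to 6 hops. The per-hop counts show the interface rings;
hop distance 0 is the interface itself.
"""

from pannet_ips import (find_largest_troi, select_representative_patches,
                        synthesize_tissue_map)
from pannet_ips.patch_selection import selection_summary

grid = synthesize_tissue_map(slide_score=4, grid_shape=(20, 20),
                             roughness=0.05, seed=7)
troi = find_largest_troi(grid)
patches = select_representative_patches(grid, max_hops=6, slide_id="demo")

summary = selection_summary(patches, troi)
print(f"tumor region: {summary['troi_size']} patches")
print(f"selected: {summary['n_selected']} "
      f"(border d=0: {summary['border_count']})")
print("patches per hop distance:")
for d, n in summary["per_hop_counts"].items():
    print(f"  d={d}: {n}")
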