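"""Generate a small synthetic PanNET cohort and inspect its composition.

Each case carries three slides; each slide has a 1-5 infiltration score and
the case label (IPS1/IPS2/IPS3) follows from the total of the three scores
(3-6 / 7-9 / 10-15). The printed summary shows the per-class case counts
and percentages, and one slide's tissue-map composition.
"""

import collections

from pannet_ips import SyntheticCohortConfig, generate_cohort
from pannet_ips.fixtures import cohort_class_summary
from pannet_ips.labels import TISSUE_NAMES

cfg = SyntheticCohortConfig(n_cases=35, grid_shape=(14, 14), seed=42)
cases, slides = generate_cohort(cfg)

print(f"cohort: {len(cases)} cases, {len(slides)} slides")
for label, row in cohort_class_summary(cases).items():
    print(f"  {label}: {row['count']:2d} cases ({row['percent']}%)")

slide = slides[0]
counts = collections.Counter(slide.tissue_map.ravel().tolist())
print(f"\nslide {slide.slide_id} (score {slide.slide_score}) tissue map:")
for code, n in sorted(counts.items()):
    print(f"  {TISSUE_NAMES[code]:>10}: {n} patches")
print(f"  nuclei in {len(slide.nuclei)} tissue patches")
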