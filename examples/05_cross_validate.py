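"""Case-level stratified cross-validation of the full scoring pipeline.

All three slides of a case share a fold; feature standardization is fit on
training folds only. The report aggregates case-level predictions across
folds and gives the weighted F1 as mean +/- std over the per-fold runs.
"""

from pannet_ips import (GNNConfig, GraphBuildConfig, build_case_bags,
                        generate_cohort, make_fold_plan,
                        run_cross_validation)
from pannet_ips.fixtures import easy_cohort_config

cfg = easy_cohort_config(n_cases=40, seed=2)
cases, slides = generate_cohort(cfg)
bags = build_case_bags(cases, slides, GraphBuildConfig(max_hops=2))
labels = {c.case_id: c.ips_label for c in cases}

plan = make_fold_plan(labels, n_folds=5, runs_per_fold=1, seed=0)
report = run_cross_validation(bags, labels, plan,
                              GNNConfig(epochs=25, seed=0))
print(report)
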