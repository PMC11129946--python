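"""Re-parametrize predictor cutoffs by maximizing Youden's J.

Published cutoffs target disease pathogenicity; on pharmacogenomic
labels the informedness-optimal cutoff usually differs.  Five-fold
cross-validation shows how much of the gain survives on held-out
variants.
"""

from apf2 import (
    crossvalidate_threshold,
    default_config,
    get_algorithm,
    simulate_labeled_scores,
)

cfg = default_config(seed=1)
table, labels = simulate_labeled_scores(cfg)

for name in table.algorithms:
    cv = crossvalidate_threshold(table, labels, get_algorithm(name), k=5, seed=1)
    f = cv.final_fit
    print(
        f"{name:18s} cutoff {get_algorithm(name).threshold:>8.4g} -> "
        f"{f.optimized_threshold:>8.4g}   J {f.J_conventional:.2f} -> "
        f"{f.J_optimized:.2f}   mean held-out dJ "
        f"{cv.mean_validation_delta_J:+.2f}"
    )

print(
    "\nThe optimized cutoff maximizes J = sensitivity + specificity - 1 "
    "on the full set; the last column is the mean J improvement on "
    "held-out folds (positive = the re-parametrization generalizes)."
)
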