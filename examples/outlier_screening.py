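"""Cook's-distance influence screening with the 3x-mean rule.

Twenty concordant effect sizes plus one aberrant record: the influence
pass computes leave-one-out Cook's distances, flags records whose D
exceeds three times the mean, and refits without them.
"""

import numpy as np

from symmeta import ModelSpec, apply_outlier_rule, fit_reml

rng = np.random.default_rng(0)
y = np.concatenate([rng.normal(0.5, 0.1, 20), [5.0]])
spec = ModelSpec(
    y=y,
    v=np.full(21, 0.4),
    X=np.ones((21, 1)),
    column_names=["intercept"],
    study=np.arange(21),
    record_ids=[f"E{i}" for i in range(21)],
)

fit = fit_reml(spec)
report = apply_outlier_rule(spec, fit)

print(f"mean D = {report.mean_d:.4f}, threshold (3x mean) = {report.threshold:.4f}")
print(f"max D = {report.d.max():.4f} at record {report.record_ids[report.d.argmax()]}")
print(f"flagged: {report.flagged}")
print(
    f"intercept with all records: {fit.beta[0]:.3f}; "
    f"with outliers removed: {report.refit.beta[0]:.3f}"
)
print()
print(
    "The aberrant record dominates the mean; after its removal the pooled\n"
    "estimate returns to the concordant records' level (~0.5). Reports always\n"
    "carry both fits side by side."
)
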