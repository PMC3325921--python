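"""Bench-assay statistics: qPCR fold change, comet OTM, regression, MN rate.

Small worked examples of the closed-form statistics used to validate a
DNA-damage biomarker: 2^-ddCt relative quantification, olive tail moment,
expression-vs-damage linear regression and micronucleus frequency.
"""

from gtxscore import (
    CometRecord,
    CtRecord,
    ddct_fold_change,
    dose_response_regression,
    mean_olive_tail_moment,
    micronucleus_frequency,
)

# qPCR: target Ct drops by 2 cycles relative to the reference -> 4-fold
fold = ddct_fold_change(CtRecord(
    treated_target=25.0, treated_reference=20.0,
    control_target=27.0, control_reference=20.0,
))
print(f"2^-ddCt fold change: {fold:.1f}x (target induced 4-fold vs control)")

# Comet assay: mean olive tail moment over scored cells of one group
comets = [CometRecord.from_percent(40.0, 25.0),
          CometRecord.from_percent(55.0, 40.0),
          CometRecord.from_percent(12.0, 5.0)]
print(f"Mean olive tail moment: {mean_olive_tail_moment(comets):.2f} um")

# Dose-response: per-dose mean expression (folds of control) vs mean OTM
expr = [1.0, 2.1, 4.2, 7.9]
otm = [0.6, 2.3, 5.1, 10.2]
fit = dose_response_regression(expr, otm)
print(f"OLS: damage = {fit.slope:.2f} * expression + {fit.intercept:.2f}, "
      f"r^2 = {fit.r_squared:.3f} (n = {fit.n})")

# Micronucleus test: scored in 1000 cells
frac, per_1000 = micronucleus_frequency(23, 1000)
print(f"Micronucleus frequency: {per_1000:.0f} per 1000 cells "
      f"(fraction {frac:.3f})")
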