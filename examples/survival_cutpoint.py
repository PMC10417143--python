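"""Optimal expression cutpoint for survival by maximum Youden's index.

Simulates a 400-subject cohort whose hazard jumps by a factor of 6 above
expression 25, scans every admissible cutoff (midpoints between observed
expression values), and selects the one maximizing J = sensitivity +
specificity - 1 against vital status.  The covariate-adjusted Cox model
(age, sex, smoking, alcohol) gives the group log hazard ratio at the
selected cutoff, and the log-rank test compares the two survival curves.
"""

import numpy as np

from layerquant import km_logrank, make_survival_table, scan_cutoffs

table = make_survival_table(
    n=400, true_cutoff=25.0, hazard_ratio=6.0, censor_rate=0.2, seed=11
)
scan = scan_cutoffs(table)

print(f"candidate cutoffs scanned: {len(scan.table)}")
print(f"selected cutoff: {scan.selected_cutoff:g} (planted: 25)")
print(f"maximum Youden J: {scan.j_max:.3f}")
print(
    f"adjusted Cox log-HR at cutoff: {scan.fit.coef:.3f} +/- {scan.fit.se:.3f} "
    f"(planted log 6 = {np.log(6):.3f}), Wald p = {scan.fit.p:.3g}"
)

km = km_logrank(table, (table["expression"] > scan.selected_cutoff).to_numpy())
print(f"log-rank chi-square = {km.statistic:.1f}, p = {km.p:.3g}")
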