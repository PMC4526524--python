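"""Phenotype-level statistics: detectable sperm-count difference and fold changes.

The study design fixes per-group size, noise level, test level and power;
the power t-test then tells you the smallest group-mean difference (in
millions of spermatozoa per ml) the design can reliably detect.
"""

from mbddmr.powerstats import (
    GroupStats,
    PowerSpec,
    fold_change_display,
    minimal_detectable_delta,
    welch_t_test,
)

spec = PowerSpec(n=8, sd=3.0, alpha=0.05, power=0.80)
delta = minimal_detectable_delta(spec)
print(f"minimal detectable difference: {delta:.3f} mio/ml (display: {round(delta, 1)})")
# ~4.5 mio/ml: any true group difference smaller than this would be missed
# more than 20% of the time with 8 animals per arm.

fc_sensitive = fold_change_display(12.1, 21.3)
fc_resistant = fold_change_display(17.80, 17.96)
print(f"fold change, sensitive strain (DEHP/control): {fc_sensitive}")
print(f"fold change, resistant strain (DEHP/control): {fc_resistant}")
# 0.6 means a 40% drop in sperm production under prenatal DEHP exposure in
# the sensitive background; 1.0 means no detectable effect in the resistant one.

t, df, p = welch_t_test(GroupStats(21.3, 3.0, 8), GroupStats(12.1, 5.0, 8))
print(f"Welch t-test on the group summaries: t={t:.2f}, df={df:.1f}, p={p:.2g}")
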