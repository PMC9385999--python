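"""Mixed-design ANOVA with Bonferroni post-hocs on a synthetic amplitude table.

Two groups of subjects measured across stimulus levels (a between x within
design): the group effect is tested against subjects-within-groups, level and
interaction against the within-subject residual, and the groups are compared
at each level with Bonferroni-adjusted t-tests.
"""

import numpy as np
import pandas as pd

from otokit import stats

rng = np.random.default_rng(5)
rows = []
for g, offset in (("control", 0.0), ("loss", -0.6)):
    for s in range(8):
        subject_effect = rng.normal(0, 0.2)
        for level in (50, 60, 70, 80, 90):
            rows.append(
                {
                    "subject": f"{g}{s}",
                    "genotype": g,
                    "level": level,
                    "value": 0.02 * level + offset + subject_effect + rng.normal(0, 0.1),
                }
            )
table = pd.DataFrame(rows)

report = stats.rm_anova(table, between="genotype", within="level")
print("ANOVA table:")
print(report.table.to_string(index=False))
print("\nper-level Bonferroni post-hocs:")
print(report.posthoc.to_string(index=False))

t = stats.two_sample_t(
    table.query("genotype == 'control'")["value"],
    table.query("genotype == 'loss'")["value"],
)
print(f"\npooled two-sample t-test on all values: t = {t.t:.2f}, df = {t.df:.0f}, p = {t.p:.2g}")
print("-> the group offset shows up as the 'between' effect and in every post-hoc row.")
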