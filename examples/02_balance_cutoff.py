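"""The core balance rule on the bundled published worksheets.

A cutoff on the nomogram malignancy probability is 'balanced' for a given
complication severity when missed malignancies (FN) equal the
complication-weighted count of unnecessary surgeries (FP x rate).  The
published worksheets carry (cutoff, FP, FN) for each surgery group; the
selection rule picks the row nearest to equality.
"""

from ipmn_balance import select_cutoff
from ipmn_balance.datasets import dp_worksheet, pd_worksheet

for table in (pd_worksheet(), dp_worksheet()):
    print(f"\n{table.group} group (grid of {len(table.rows)} published rows):")
    for severity in ("IV", "IIIb", "IIIa", "II"):
        rate = table.rate_set.rate_ge[severity]
        sel = select_cutoff(table, severity)
        print(
            f"  complications >= grade {severity:<4} (rate {100 * rate:4.1f}%):"
            f" cutoff {sel.cutoff:g}%  |FN - FP x rate| = {sel.residual:.3f}"
        )

# Riskier complications justify a higher bar for surgery: the cutoff rises
# with the complication rate (13 -> 41% for PD, 14 -> 27% for DP), and the
# higher-risk PD operation gets a higher cutoff than DP at every severity.
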