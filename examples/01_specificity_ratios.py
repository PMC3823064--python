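"""Classify aminotransferases from published specificity constants.

The substrate preference of a subfamily Ialpha aminotransferase is the
ratio of specificity constants kcat/Km for the aspartate versus the
phenylalanine reaction: ratio > 1 is an AATase, < 1 a TATase.  Here we
re-derive the ratio column from the published kcat/Km values.
"""

from specswap import specificity_ratio_from_constants
from specswap.reference_data import TABLE_SPECIFICITY_CONSTANTS

print(f"{'enzyme':8s} {'kcat/Km Asp':>12s} {'kcat/Km Phe':>12s} {'ratio':>8s}  label")
for row in TABLE_SPECIFICITY_CONSTANTS:
    call = specificity_ratio_from_constants(row.asp_kcat_over_Km, row.phe_kcat_over_Km)
    print(
        f"{row.enzyme:8s} {row.asp_kcat_over_Km:12,.0f} {row.phe_kcat_over_Km:12,.1f} "
        f"{call.rounded_ratio:8g}  {call.label}"
    )

# The ratio column is the Asp:Phe quotient rounded to two significant
# figures; every label follows the >1 / <1 rule, and three of the newly
# characterized enzymes (GicAT, TbcAT, VcAT) come out as TATases.
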