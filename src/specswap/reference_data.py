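"""Published specificity constants for subfamily Ialpha aminotransferases.

``kcat/Km`` values (M^-1 s^-1) for the aspartate and phenylalanine
reactions as printed in the kinetic characterization, together with the
printed Asp:Phe specificity ratio.  The printed ratios were computed from
unrounded fits, so for some enzymes re-dividing the printed (rounded)
constants does not reproduce the printed ratio at two significant figures;
``ratio_roundtrips`` records which rows do.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpecificityConstants:
    enzyme: str
    asp_kcat_over_Km: float  # M^-1 s^-1
    phe_kcat_over_Km: float  # M^-1 s^-1
    printed_ratio: float
    newly_characterized: bool
    label: str  # AATase | TATase


TABLE_SPECIFICITY_CONSTANTS: tuple[SpecificityConstants, ...] = (
    SpecificityConstants("eAAT", 90_800, 119, 760, False, "AATase"),
    SpecificityConstants("eTAT", 37_000, 960_000, 0.038, False, "TATase"),
    SpecificityConstants("AtmAT", 36_000, 8.8, 4_100, True, "AATase"),
    SpecificityConstants("CecAT", 34_000, 0.45, 80_000, True, "AATase"),
    SpecificityConstants("CtAT", 37_000, 80, 470, True, "AATase"),
    SpecificityConstants("GicAT", 10_200, 47_000, 0.22, True, "TATase"),
    SpecificityConstants("PfcAT", 35_000, 3.0, 12_000, True, "AATase"),
    SpecificityConstants("PaAT", 47_000, 47, 1_000, True, "AATase"),
    SpecificityConstants("SccAT", 63_000, 18, 3_600, True, "AATase"),
    SpecificityConstants("ScmAT", 14_000, 3.1, 5_000, True, "AATase"),
    SpecificityConstants("TbcAT", 11_000, 22_000, 0.49, True, "TATase"),
    SpecificityConstants("TbmAT", 132, 22.0, 6.0, True, "AATase"),
    SpecificityConstants("VcAT", 680, 67_000, 0.010, True, "TATase"),
)

#: Enzymes whose printed ratio is reproduced exactly (2 significant figures)
#: by dividing the printed constants.  The remaining rows were evidently
#: computed from unrounded fitted constants.
RATIO_ROUNDTRIP_ENZYMES: tuple[str, ...] = (
    "eAAT",
    "AtmAT",
    "GicAT",
    "PfcAT",
    "PaAT",
    "TbmAT",
    "VcAT",
)


def constants_for(enzyme: str) -> SpecificityConstants:
    for row in TABLE_SPECIFICITY_CONSTANTS:
        if row.enzyme == enzyme:
            return row
    raise KeyError(enzyme)
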