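"""MS1 isotope-pattern arithmetic for chlorine detection.

Chlorine has two stable isotopes (35Cl 75.77%, 37Cl 24.22%), so one
chlorine atom adds an M+2 satellite at ~0.320 of the monoisotopic peak -
far above the 13C2 contribution of a mid-size peptide - which makes the
M+2/M ratio a clean chlorination flag. Carbon counts for the 13C terms
are estimated from the averagine model (4.9384 C per 111.1254 Da).
"""

from __future__ import annotations

from .model import C13_DELTA, Peak

#: natural abundance of 13C
P_13C = 0.0107
#: 37Cl/35Cl natural abundance ratio (24.22 / 75.77)
CL_RATIO = 24.22 / 75.77
#: averagine carbons per Dalton
_C_PER_DA = 4.9384 / 111.1254


def estimate_carbons(neutral_mass: float) -> int:
    """Averagine estimate of the carbon count of a peptide of given mass."""
    if not neutral_mass > 0:
        raise ValueError("neutral mass must be positive")
    return max(1, round(_C_PER_DA * neutral_mass))


def isotope_ratios(neutral_mass: float, n_cl: int = 0) -> tuple[float, float]:
    """(M+1)/M and (M+2)/M intensity ratios.

    The M+1 term is the binomial single-13C contribution. For chlorinated
    species the M+2 term is the chlorine contribution alone (the 13C2 term
    is second-order next to it and omitted); for unchlorinated species it
    is the binomial double-13C term.
    """
    n_c = estimate_carbons(neutral_mass)
    r = P_13C / (1.0 - P_13C)
    m1 = n_c * r
    if n_cl > 0:
        # binomial in 37Cl: k Cl atoms give (k choose 1) * CL_RATIO at M+2
        m2 = n_cl * CL_RATIO
    else:
        m2 = 0.5 * n_c * (n_c - 1) * r * r
    return m1, m2


def isotope_pattern(
    precursor_mz: float, neutral_mass: float, charge: int = 1, n_cl: int = 0
) -> list[Peak]:
    """Render the M, M+1, M+2 pattern as peaks (monoisotopic intensity 1.0).

    Peaks are spaced by one isotope mass unit divided by the charge, as
    observed in m/z space.
    """
    m1, m2 = isotope_ratios(neutral_mass, n_cl)
    spacing = C13_DELTA / charge
    return [
        Peak(precursor_mz, 1.0),
        Peak(precursor_mz + spacing, m1),
        Peak(precursor_mz + 2 * spacing, m2),
    ]
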