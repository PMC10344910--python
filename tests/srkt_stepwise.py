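"""Independent stepwise SRK/T oracle.

This file is a deliberately plain, scalar-by-scalar transliteration of the
published SRK/T formula chain (Retzlaff, Sanders & Kraff 1990, with errata).
It is written and kept independently of ``iolsvr.srkt`` so that the two can
be compared as implementation vs. oracle; do not refactor one in terms of
the other.
"""

import math

KERATOMETRIC_INDEX_NUMERATOR = 337.5  # (1.3375 - 1) * 1000
NA = 1.336
NC_MINUS_1 = 0.333
VERTEX_MM = 12.0


def oracle_refraction(axl, cr, a_constant, iol_power):
    """Spectacle-plane predicted refraction, one explicit step at a time."""
    L = axl
    r = cr
    A = a_constant
    P = iol_power

    K = KERATOMETRIC_INDEX_NUMERATOR / r

    if L <= 24.2:
        LCOR = L
    else:
        LCOR = -3.446 + 1.715 * L - 0.0237 * L * L

    Cw = -5.41 + 0.58412 * LCOR + 0.098 * K

    radicand = r * r - (Cw * Cw) / 4.0
    if radicand < 0.0:
        radicand = 0.0
    H = r - math.sqrt(radicand)

    ACD_const = 0.62467 * A - 68.747
    ELP = H + ACD_const - 3.336

    RETHICK = 0.65696 - 0.02029 * L
    LOPT = L + RETHICK

    V = VERTEX_MM
    na = NA
    ncm1 = NC_MINUS_1

    numerator = 1000.0 * na * (na * r - ncm1 * LOPT) \
        - P * (LOPT - ELP) * (na * r - ncm1 * ELP)
    denominator = na * (V * (na * r - ncm1 * LOPT) + LOPT * r) \
        - 0.001 * P * (LOPT - ELP) * (V * (na * r - ncm1 * ELP) + ELP * r)
    return numerator / denominator


def oracle_emmetropia_power(axl, cr, a_constant):
    """IOL power giving zero predicted refraction, from the closed form."""
    L = axl
    r = cr
    A = a_constant

    K = KERATOMETRIC_INDEX_NUMERATOR / r
    if L <= 24.2:
        LCOR = L
    else:
        LCOR = -3.446 + 1.715 * L - 0.0237 * L * L
    Cw = -5.41 + 0.58412 * LCOR + 0.098 * K
    radicand = r * r - (Cw * Cw) / 4.0
    if radicand < 0.0:
        radicand = 0.0
    H = r - math.sqrt(radicand)
    ACD_const = 0.62467 * A - 68.747
    ELP = H + ACD_const - 3.336
    RETHICK = 0.65696 - 0.02029 * L
    LOPT = L + RETHICK

    na = NA
    ncm1 = NC_MINUS_1
    return 1000.0 * na * (na * r - ncm1 * LOPT) \
        / ((LOPT - ELP) * (na * r - ncm1 * ELP))


def oracle_chain(axl, cr, a_constant):
    """All intermediates as a dict, for field-by-field comparison."""
    L = axl
    r = cr
    A = a_constant
    K = KERATOMETRIC_INDEX_NUMERATOR / r
    if L <= 24.2:
        LCOR = L
    else:
        LCOR = -3.446 + 1.715 * L - 0.0237 * L * L
    Cw = -5.41 + 0.58412 * LCOR + 0.098 * K
    radicand = r * r - (Cw * Cw) / 4.0
    if radicand < 0.0:
        radicand = 0.0
    H = r - math.sqrt(radicand)
    ACD_const = 0.62467 * A - 68.747
    ELP = H + ACD_const - 3.336
    RETHICK = 0.65696 - 0.02029 * L
    LOPT = L + RETHICK
    return {
        "k_diopters": K,
        "lcor": LCOR,
        "cw": Cw,
        "h": H,
        "acd_const": ACD_const,
        "elp": ELP,
        "rethick": RETHICK,
        "lopt": LOPT,
    }
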