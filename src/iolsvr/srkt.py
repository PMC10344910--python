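"""SRK/T refraction prediction and IOL power calculation.

Implements the third-generation theoretical vergence formula of Retzlaff,
Sanders and Kraff (the SRK/T formula, with published errata): corneal power
from the radius of curvature, corrected axial length, corneal height, an
A-constant-derived estimated lens position (ELP), and the thin-lens vergence
equation giving the spectacle-plane refraction for a given IOL power.

All numeric coefficients live in :class:`SRKTConstants` so that published
coefficient variants can be swapped in one place.  Computation is vectorized:
every operation accepts scalars or equal-length NumPy arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import (
    InvalidConfigError,
    InvalidGeometryError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SRKTConstants",
    "EyeRecord",
    "SRKTResult",
    "DEFAULT_CONSTANTS",
    "keratometry_from_radius",
    "acd_constant_from_a",
    "corrected_axial_length",
    "srkt_chain",
    "predicted_refraction",
    "emmetropia_power",
    "select_iol_power",
    "predict_cohort",
]


@dataclass(frozen=True)
class SRKTConstants:
    """The published SRK/T coefficient set.

    ``keratometric_index`` converts corneal radius (mm) to keratometry via
    K = 1000*(n_k - 1)/r = 337.5/r.  ``na`` is the aqueous/vitreous index,
    ``ncm1`` the corneal index minus one as used in the vergence equation,
    and ``vertex`` the spectacle vertex distance in mm.
    """

    keratometric_index: float = 1.3375
    na: float = 1.336
    ncm1: float = 0.333
    vertex: float = 12.0
    acd_const_slope: float = 0.62467
    acd_const_intercept: float = -68.747
    elp_offset_shift: float = 3.336
    rethick_intercept: float = 0.65696
    rethick_slope: float = -0.02029
    lcor_threshold: float = 24.2
    lcor_coeffs: tuple[float, float, float] = (-3.446, 1.715, -0.0237)
    cw_coeffs: tuple[float, float, float] = (-5.41, 0.58412, 0.098)


DEFAULT_CONSTANTS = SRKTConstants()


@dataclass
class EyeRecord:
    """One eye's biometry, implanted IOL and achieved refraction.

    Units: lengths in mm, powers and refractions in diopters.  ``mrse`` is
    the postoperative manifest refraction spherical equivalent; fields that
    are not yet known (e.g. before IOL assignment) are ``None``.
    """

    eye_id: str
    axl: float
    cr: float
    acd: Optional[float] = None
    lt: Optional[float] = None
    wtw: Optional[float] = None
    a_constant: Optional[float] = None
    iol_power: Optional[float] = None
    mrse: Optional[float] = None
    iol_model: Optional[str] = None
    haptic_type: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.axl > 0:
            raise InvalidInputError(f"{self.eye_id}: axl must be > 0, got {self.axl}")
        if not self.cr > 0:
            raise InvalidInputError(f"{self.eye_id}: cr must be > 0, got {self.cr}")
        if self.a_constant is not None and not 110.0 <= self.a_constant <= 125.0:
            raise InvalidInputError(
                f"{self.eye_id}: a_constant {self.a_constant} outside [110, 125]"
            )
        if self.iol_power is not None and not -5.0 <= self.iol_power <= 40.0:
            raise InvalidInputError(
                f"{self.eye_id}: iol_power {self.iol_power} outside [-5, 40]"
            )
        if self.haptic_type is not None and self.haptic_type not in (
            "open_loop",
            "plate",
        ):
            raise InvalidInputError(
                f"{self.eye_id}: haptic_type must be open_loop or plate"
            )


@dataclass
class SRKTResult:
    """The SRK/T intermediate chain plus (optionally) prediction outputs.

    Fields mirror the formula's published symbols: ``k_diopters`` (K),
    ``lcor`` (corrected axial length), ``cw`` (computed corneal width),
    ``h`` (corneal height), ``elp`` (estimated lens position / ACDest),
    ``rethick`` (retinal thickness correction), ``lopt`` (optical axial
    length).  ``pred_refraction`` and ``emme_power`` are filled by the
    higher-level prediction helpers.
    """

    k_diopters: np.ndarray
    lcor: np.ndarray
    cw: np.ndarray
    h: np.ndarray
    acd_const: np.ndarray
    elp: np.ndarray
    rethick: np.ndarray
    lopt: np.ndarray
    pred_refraction: Optional[np.ndarray] = None
    emme_power: Optional[np.ndarray] = None
    clamped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def keratometry_from_radius(
    cr, constants: SRKTConstants = DEFAULT_CONSTANTS
):
    """Keratometry K (D) from the corneal radius of curvature (mm)."""
    cr = np.asarray(cr, dtype=float)
    if np.any(cr <= 0):
        raise InvalidInputError("corneal radius must be positive")
    return 1000.0 * (constants.keratometric_index - 1.0) / cr


def acd_constant_from_a(
    a_constant, constants: SRKTConstants = DEFAULT_CONSTANTS
):
    """The ACD-constant (mm) from the IOL A-constant (affine map)."""
    a = np.asarray(a_constant, dtype=float)
    if np.any((a < 110.0) | (a > 125.0)):
        raise InvalidInputError("a_constant outside [110, 125]")
    return constants.acd_const_slope * a + constants.acd_const_intercept


def corrected_axial_length(
    axl, constants: SRKTConstants = DEFAULT_CONSTANTS
):
    """Corrected axial length LCOR (mm): identity below the long-eye
    threshold, the published quadratic above it."""
    axl = np.asarray(axl, dtype=float)
    if np.any(axl <= 0):
        raise InvalidInputError("axial length must be positive")
    c0, c1, c2 = constants.lcor_coeffs
    quad = c0 + c1 * axl + c2 * axl * axl
    return np.where(axl <= constants.lcor_threshold, axl, quad)


def srkt_chain(
    axl, cr, a_constant, constants: SRKTConstants = DEFAULT_CONSTANTS
) -> SRKTResult:
    """Evaluate the SRK/T intermediate chain for one eye or a batch.

    A negative corneal-height radicand (geometrically impossible corneal
    width) is clamped to zero — giving H = r — and logged, never raised.
    """
    axl = np.asarray(axl, dtype=float)
    cr = np.asarray(cr, dtype=float)
    k = keratometry_from_radius(cr, constants)
    lcor = corrected_axial_length(axl, constants)
    w0, w1, w2 = constants.cw_coeffs
    cw = w0 + w1 * lcor + w2 * k
    radicand = cr * cr - cw * cw / 4.0
    clamped = radicand < 0.0
    n_clamped = int(np.count_nonzero(clamped))
    if n_clamped:
        logger.warning(
            "corneal height radicand negative for %d eye(s); clamped to H = r",
            n_clamped,
        )
    h = cr - np.sqrt(np.where(clamped, 0.0, radicand))
    acd_const = acd_constant_from_a(a_constant, constants)
    elp = h + (acd_const - constants.elp_offset_shift)
    rethick = constants.rethick_intercept + constants.rethick_slope * axl
    lopt = axl + rethick
    return SRKTResult(
        k_diopters=k,
        lcor=lcor,
        cw=cw,
        h=h,
        acd_const=np.broadcast_to(acd_const, np.broadcast_shapes(axl.shape, np.shape(acd_const))).copy()
        if axl.shape
        else acd_const,
        elp=elp,
        rethick=rethick,
        lopt=lopt,
        clamped=np.atleast_1d(clamped),
    )


def _vergence_refraction(cr, elp, lopt, iol_power, constants: SRKTConstants):
    na = constants.na
    ncm1 = constants.ncm1
    v = constants.vertex
    p = np.asarray(iol_power, dtype=float)
    x1 = na * cr - ncm1 * lopt
    x2 = na * cr - ncm1 * elp
    num = 1000.0 * na * x1 - p * (lopt - elp) * x2
    den = na * (v * x1 + lopt * cr) - 0.001 * p * (lopt - elp) * (v * x2 + elp * cr)
    if np.any(den == 0.0):
        raise InvalidGeometryError("vergence denominator is zero (degenerate optics)")
    return num / den


def predicted_refraction(
    axl, cr, a_constant, iol_power, constants: SRKTConstants = DEFAULT_CONSTANTS
):
    """SRK/T predicted spectacle-plane refraction (D) for a given IOL power."""
    chain = srkt_chain(axl, cr, a_constant, constants)
    cr = np.asarray(cr, dtype=float)
    return _vergence_refraction(cr, chain.elp, chain.lopt, iol_power, constants)


def emmetropia_power(
    axl, cr, a_constant, constants: SRKTConstants = DEFAULT_CONSTANTS
):
    """IOL power (D) that zeroes the predicted spectacle refraction."""
    chain = srkt_chain(axl, cr, a_constant, constants)
    cr = np.asarray(cr, dtype=float)
    if np.any(chain.lopt <= chain.elp):
        raise InvalidGeometryError("optical axial length must exceed the ELP")
    x1 = constants.na * cr - constants.ncm1 * chain.lopt
    x2 = constants.na * cr - constants.ncm1 * chain.elp
    return 1000.0 * constants.na * x1 / ((chain.lopt - chain.elp) * x2)


def select_iol_power(
    axl,
    cr,
    a_constant,
    target_refraction,
    power_min: float = 5.0,
    power_max: float = 30.0,
    power_step: float = 0.5,
    constants: SRKTConstants = DEFAULT_CONSTANTS,
):
    """Pick the catalogue power whose predicted refraction is closest to the
    target; ties break toward the higher power (the more myopic outcome).

    Scalar inputs give a scalar; array inputs give per-eye powers.
    """
    if power_max < power_min or power_step <= 0:
        raise InvalidConfigError("empty or invalid power grid")
    grid = np.round(
        np.arange(power_min, power_max + power_step / 2.0, power_step), 10
    )
    axl_a = np.atleast_1d(np.asarray(axl, dtype=float))
    cr_a = np.atleast_1d(np.asarray(cr, dtype=float))
    a_a = np.atleast_1d(np.asarray(a_constant, dtype=float))
    tgt = np.broadcast_to(
        np.asarray(target_refraction, dtype=float), axl_a.shape
    )
    # refraction for every (eye, grid power) pair
    refs = predicted_refraction(
        axl_a[:, None],
        cr_a[:, None],
        a_a[:, None],
        grid[None, :],
        constants,
    )
    dist = np.abs(refs - tgt[:, None])
    # ties toward higher power: scan the grid from the top
    rev = dist[:, ::-1]
    idx_rev = np.argmin(rev, axis=1)
    idx = grid.size - 1 - idx_rev
    chosen = grid[idx]
    at_edge = (idx == grid.size - 1) | (idx == 0)
    unreachable = at_edge & (dist[np.arange(len(idx)), idx] > abs(power_step))
    if np.any(unreachable):
        logger.warning(
            "target refraction out of achievable range for %d eye(s); "
            "returning the grid boundary power",
            int(np.count_nonzero(unreachable)),
        )
    if np.isscalar(axl) or np.ndim(axl) == 0:
        return float(chosen[0])
    return chosen


def predict_cohort(df, constants: SRKTConstants = DEFAULT_CONSTANTS):
    """Append ``srkt_pred_d`` and ``emme_power_d`` columns to a cohort table.

    Expects the canonical cohort columns (``axl_mm``, ``cr_mm``,
    ``a_constant``, ``iol_power_d``).  Returns a copy; never mutates.
    """
    out = df.copy()
    out["srkt_pred_d"] = predicted_refraction(
        df["axl_mm"].to_numpy(),
        df["cr_mm"].to_numpy(),
        df["a_constant"].to_numpy(),
        df["iol_power_d"].to_numpy(),
        constants,
    )
    out["emme_power_d"] = emmetropia_power(
        df["axl_mm"].to_numpy(),
        df["cr_mm"].to_numpy(),
        df["a_constant"].to_numpy(),
        constants,
    )
    return out
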