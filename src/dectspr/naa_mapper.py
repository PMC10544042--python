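"""VMI-pair SPR mapping by Jackson-Hawkes inversion.

Given two virtual monoenergetic images (VMIs) at energies E1 and E2 expressed
as linear attenuation relative to water, each voxel is inverted for the
effective atomic number Zeff (root of the two-energy Jackson-Hawkes
consistency equation), the relative electron density follows in closed form,
ln I from the Yang parametrization and SPR from the Bethe ratio.  A reference
VMI (74 keV by default) segments the volume into lung / soft tissue / bone so
that a class-specific VMI pair can be used per voxel.

Two solver paths are provided and tested against each other:

* :func:`invert_zeff` - scalar bounded minimization of the squared residual
  (SLSQP, start 5, bounds [4, 54]) with a grid-scan fallback, and
* :class:`ZeffInverter` - a vectorized inversion through a precomputed
  monotone table of the per-electron cross-section ratio, used for volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from .physics_core import (
    BETHE_DEFAULT,
    YANG_DEFAULT,
    BetheConstants,
    JHBasis,
    YangConstants,
    hu_to_rel_atten,
    spr_bethe,
    water_per_electron_xs,
    yang_lnI,
)

__all__ = [
    "ConfigurationError",
    "TissueClassThresholds",
    "PairAssignment",
    "default_pair_assignment",
    "ZeffInverter",
    "invert_zeff",
    "invert_zeff_grid",
    "red_from_pair",
    "segment_tissue_classes",
    "map_spr_naa",
    "TISSUE_CLASSES",
]

TISSUE_CLASSES = ("lung", "soft", "bone")


class ConfigurationError(KeyError):
    """The VMI stack or pair assignment is inconsistent."""


@dataclass(frozen=True)
class TissueClassThresholds:
    """HU segmentation limits on the reference VMI.

    Lung is (-inf, lung_upper), soft tissue the closed interval
    [lung_upper, bone_lower], bone (bone_lower, inf).
    """

    lung_upper_hu: float = -200.0
    bone_lower_hu: float = 150.0
    reference_keV: float = 74.0

    def __post_init__(self):
        if self.lung_upper_hu >= self.bone_lower_hu:
            raise ConfigurationError("lung upper bound must lie below bone lower bound")


@dataclass(frozen=True)
class PairAssignment:
    """Tissue class -> (E1, E2) VMI pair in keV."""

    pairs: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for cls, (e1, e2) in self.pairs.items():
            if cls not in TISSUE_CLASSES:
                raise ConfigurationError(f"unknown tissue class {cls!r}")
            if e1 == e2:
                raise ConfigurationError(f"{cls}: E1 must differ from E2")
            for e in (e1, e2):
                if not 40.0 <= e <= 140.0:
                    raise ConfigurationError(f"{cls}: energy {e} outside [40, 140] keV")

    def __getitem__(self, cls: str) -> tuple[float, float]:
        return self.pairs[cls]

    def energies(self) -> set[float]:
        return {e for pair in self.pairs.values() for e in pair}


def default_pair_assignment() -> PairAssignment:
    """Per-class VMI pairs selected by the packaged pair optimization.

    Output of ranking all candidate pairs by measured SPR RMSE pooled over
    the two default synthetic phantoms at medium dose (see vmi_optimizer);
    frozen here so mapping runs do not require re-optimizing.
    """
    return PairAssignment(
        {"lung": (40.0, 50.0), "soft": (40.0, 70.0), "bone": (40.0, 115.0)}
    )


# ---------------------------------------------------------------------------
# Zeff inversion
# ---------------------------------------------------------------------------


def jh_forward_rel_atten(zeff, red, energy_keV: float, basis: JHBasis):
    """Eq.-(1) forward model: water-relative attenuation of a (Zeff, RED) voxel."""
    return (
        np.asarray(red)
        * basis.per_electron(zeff, energy_keV)
        / water_per_electron_xs(energy_keV)
    )


def _per_electron_pair(mu1, mu2, e1, e2):
    """Water-relative attenuations -> per-electron scale (cm^2/electron).

    mu/mu_w = rho_e * e(z,E) / e_w(E); multiplying by water's per-electron
    cross section e_w(E) removes the energy-dependent water normalization so
    that the two-energy consistency equation holds in ratio form.
    """
    return (
        np.asarray(mu1, dtype=float) * water_per_electron_xs(e1),
        np.asarray(mu2, dtype=float) * water_per_electron_xs(e2),
    )


def _scaled_residual(z, m1, m2, e1, e2, basis: JHBasis):
    """Residual of the two-energy consistency equation, scaled to O(1).

    Root-equivalent to m2*(z^4 F1 + G1) - m1*(z^4 F2 + G2) = 0; dividing by
    m2 * e(z, E2) gives ratio(z) - m1/m2, which is numerically well scaled.
    """
    return basis.per_electron(z, e1) / basis.per_electron(z, e2) - m1 / m2


def invert_zeff(
    mu1: float,
    mu2: float,
    e1: float,
    e2: float,
    basis: JHBasis,
    *,
    tol: float = 1e-8,
    x0: float = 5.0,
    bounds: tuple[float, float] = (4.0, 54.0),
) -> float:
    """Scalar EAN from one VMI-pair voxel (bounded iterative solve).

    Minimizes the squared scaled residual with SLSQP from ``x0`` within
    ``bounds``; if the residual tolerance is not met, falls back to a
    0.01-step grid scan plus local refinement.  Non-bracketing inputs pin the
    result at the nearer bound (callers flag such voxels).
    """
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("relative attenuations must be positive")
    m1, m2 = _per_electron_pair(mu1, mu2, e1, e2)
    lo = max(bounds[0], basis.z_min)
    hi = min(bounds[1], basis.z_max)

    def cost(zv):
        return _scaled_residual(float(np.atleast_1d(zv)[0]), m1, m2, e1, e2, basis) ** 2

    res = optimize.minimize(
        cost, x0=[x0], method="SLSQP", bounds=[(lo, hi)], options={"ftol": 1e-14}
    )
    z = float(res.x[0])
    if cost(z) <= tol**2:
        return z
    # fallback: coarse scan + bounded local refinement
    grid = np.arange(lo, hi + 0.005, 0.01)
    r = np.abs(_scaled_residual(grid, m1, m2, e1, e2, basis))
    zc = grid[int(np.argmin(r))]
    span = (max(lo, zc - 0.02), min(hi, zc + 0.02))
    ref = optimize.minimize_scalar(cost, bounds=span, method="bounded")
    z = float(ref.x)
    if cost(z) > cost(zc):
        z = float(zc)
    return z


def invert_zeff_grid(
    mu1, mu2, e1, e2, basis: JHBasis, *, step: float = 0.001,
    bounds: tuple[float, float] = (4.0, 54.0),
) -> float:
    """Exhaustive grid-search oracle: argmin |residual| on a fixed Zeff grid."""
    m1, m2 = _per_electron_pair(mu1, mu2, e1, e2)
    lo = max(bounds[0], basis.z_min)
    hi = min(bounds[1], basis.z_max)
    grid = np.arange(lo, hi + step / 2, step)
    r = np.abs(_scaled_residual(grid, m1, m2, e1, e2, basis))
    return float(grid[int(np.argmin(r))])


class ZeffInverter:
    """Vectorized EAN inversion for one VMI pair.

    Precomputes the per-electron cross-section ratio e(z,E1)/e(z,E2) on a
    dense Zeff grid (monotone in z) and inverts it by linear interpolation of
    mu1/mu2.  Voxels whose ratio falls outside the tabulated range are pinned
    to the nearer bound and flagged.
    """

    def __init__(
        self,
        basis: JHBasis,
        e1: float,
        e2: float,
        *,
        step: float = 0.002,
        bounds: tuple[float, float] = (4.0, 54.0),
    ):
        self.e1, self.e2 = float(e1), float(e2)
        lo = max(bounds[0], basis.z_min)
        hi = min(bounds[1], basis.z_max)
        self.z_grid = np.arange(lo, hi + step / 2, step)
        ratio = basis.per_electron(self.z_grid, self.e1) / basis.per_electron(
            self.z_grid, self.e2
        )
        d = np.diff(ratio)
        if np.all(d > 0):
            self._ratio, self._z = ratio, self.z_grid
        elif np.all(d < 0):
            self._ratio, self._z = ratio[::-1], self.z_grid[::-1]
        else:
            raise ValueError(
                f"cross-section ratio not monotone in Zeff for pair "
                f"({self.e1}, {self.e2}) keV"
            )

    def __call__(self, mu1, mu2):
        """Returns (zeff, flagged) arrays matching the input shape."""
        m1, m2 = _per_electron_pair(mu1, mu2, self.e1, self.e2)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = m1 / m2
        mu1 = np.asarray(mu1, dtype=float)
        mu2 = np.asarray(mu2, dtype=float)
        bad = ~np.isfinite(r) | (mu1 <= 0) | (mu2 <= 0)
        r = np.where(bad, self._ratio[0], r)
        flagged = bad | (r < self._ratio[0]) | (r > self._ratio[-1])
        z = np.interp(r, self._ratio, self._z)
        return z, flagged


def red_from_pair(mu1, mu2, e1, e2, zeff, basis: JHBasis):
    """Closed-form relative electron density from the inverted Zeff.

    Returns (red, flagged); flagged marks voxels with a vanishing denominator.
    """
    z = np.asarray(zeff, dtype=float)
    m1, m2 = _per_electron_pair(mu1, mu2, e1, e2)
    f1 = basis.F(z, e1)
    f2 = basis.F(z, e2)
    g1 = basis.G(z, e1)
    g2 = basis.G(z, e2)
    num = m1 * f2 - m2 * f1
    den = f2 * g1 - f1 * g2
    scale = np.abs(f2 * g1) + np.abs(f1 * g2)
    flagged = np.abs(den) <= 1e-12 * scale
    red = np.where(flagged, np.nan, num / np.where(flagged, 1.0, den))
    if np.isscalar(zeff) and np.ndim(mu1) == 0:
        return float(red), bool(flagged)
    return red, flagged


# ---------------------------------------------------------------------------
# segmentation and volume mapping
# ---------------------------------------------------------------------------


def segment_tissue_classes(
    ref_vmi_hu: np.ndarray,
    thresholds: TissueClassThresholds = TissueClassThresholds(),
) -> np.ndarray:
    """Per-voxel label volume: 0 = lung, 1 = soft, 2 = bone.

    Boundary values belong to soft tissue (closed interval).
    """
    hu = np.asarray(ref_vmi_hu)
    labels = np.ones(hu.shape, dtype=np.int8)
    labels[hu < thresholds.lung_upper_hu] = 0
    labels[hu > thresholds.bone_lower_hu] = 2
    return labels


def map_spr_naa(
    vmi_stack_hu: Mapping[float, np.ndarray],
    assignment: PairAssignment,
    thresholds: TissueClassThresholds = TissueClassThresholds(),
    basis: JHBasis | None = None,
    constants: BetheConstants = BETHE_DEFAULT,
    yang: YangConstants = YANG_DEFAULT,
) -> dict[str, np.ndarray]:
    """Voxel-wise EAN / RED / SPR maps from a stack of VMIs in HU.

    Segmentation on the reference VMI picks the class pair per voxel; each
    class region then runs the Jackson-Hawkes inversion chain.  Returns
    ``{"EAN", "RED", "SPR", "flags"}``; flagged voxels (pinned Zeff or
    degenerate denominator) still carry propagated values where finite.
    """
    from .physics_core import build_jh_basis

    if basis is None:
        basis = build_jh_basis()
    needed = assignment.energies() | {thresholds.reference_keV}
    missing = sorted(e for e in needed if e not in vmi_stack_hu)
    if missing:
        raise ConfigurationError(f"VMI stack missing energies {missing} keV")

    ref = np.asarray(vmi_stack_hu[thresholds.reference_keV])
    labels = segment_tissue_classes(ref, thresholds)
    ean = np.full(ref.shape, np.nan)
    red = np.full(ref.shape, np.nan)
    flags = np.zeros(ref.shape, dtype=bool)

    for idx, cls in enumerate(TISSUE_CLASSES):
        mask = labels == idx
        if not np.any(mask):
            continue
        e1, e2 = assignment[cls]
        mu1 = hu_to_rel_atten(np.asarray(vmi_stack_hu[e1])[mask])
        mu2 = hu_to_rel_atten(np.asarray(vmi_stack_hu[e2])[mask])
        inverter = _inverter_cache(basis, e1, e2)
        z, f_inv = inverter(mu1, mu2)
        r, f_red = red_from_pair(mu1, mu2, e1, e2, z, basis)
        ean[mask] = z
        red[mask] = r
        flags[mask] = f_inv | f_red
    i_eff = np.exp(yang_lnI(ean, yang))
    spr = np.where(red > 0, red, 0.0) * _bethe_ratio(i_eff, constants)
    return {"EAN": ean, "RED": red, "SPR": spr, "flags": flags, "labels": labels}


def _bethe_ratio(i_eff_eV, constants: BetheConstants):
    # elementwise Bethe factor; NaN-safe for background voxels
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = constants.beta_sq
        num = np.log(constants.two_me_c2_MeV * b2 / ((1 - b2) * i_eff_eV * 1e-6)) - b2
        den = np.log(
            constants.two_me_c2_MeV * b2 / ((1 - b2) * constants.I_water_eV * 1e-6)
        ) - b2
        return num / den


_INVERTERS: dict[tuple[int, float, float], ZeffInverter] = {}


def _inverter_cache(basis: JHBasis, e1: float, e2: float) -> ZeffInverter:
    key = (id(basis), float(e1), float(e2))
    if key not in _INVERTERS:
        _INVERTERS[key] = ZeffInverter(basis, e1, e2)
    return _INVERTERS[key]
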