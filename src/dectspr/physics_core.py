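"""Ground-truth photon and proton physics shared by all SPR mapping methods.

This module owns:

* the packaged elemental data (partial photon mass attenuation coefficients,
  atomic masses, mean excitation energies) and the mixture rule,
* the Jackson-Hawkes per-electron parametrization
  ``mu(E) = rho_e * (Zeff^4 * F(Zeff, E) + G(Zeff, E))``
  built directly from the packaged elemental tables,
* ground-truth relative electron density (RED), effective atomic number
  (EAN), Bragg-additivity I-values, and the Bethe stopping-power ratio (SPR)
  of a material relative to water for a fixed proton energy,
* the Yang piecewise-linear ``ln I(Zeff)`` parametrization and the Hounsfield
  to relative-attenuation conversion used throughout the pipeline.

The packaged elemental cross sections are synthetic (computed from standard
analytic scattering/absorption models, see ``data/elements_synthetic.json``
and the generator script); all downstream ground truths and forward models
are computed from them, so the pipeline is self-consistent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

N_AVOGADRO = 6.02214076e23
ELECTRON_REST_MEV = 0.51099895
PROTON_REST_MEV = 938.272

__all__ = [
    "Element",
    "Material",
    "JHBasis",
    "BetheConstants",
    "YangConstants",
    "CompositionError",
    "OutOfDomainError",
    "elements",
    "element",
    "load_tissues",
    "load_inserts",
    "water",
    "mass_attenuation",
    "linear_attenuation_rel_water",
    "build_jh_basis",
    "true_red",
    "true_lnI",
    "true_ean",
    "spr_bethe",
    "yang_lnI",
    "hu_to_rel_atten",
    "rel_atten_to_hu",
    "BETHE_DEFAULT",
    "YANG_DEFAULT",
]


class CompositionError(ValueError):
    """A material composition is inconsistent or references unknown elements."""


class OutOfDomainError(ValueError):
    """A requested energy or atomic number lies outside the tabulated domain."""


# ---------------------------------------------------------------------------
# packaged data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Element:
    """One chemical element with partial mass attenuation tables (cm^2/g)."""

    symbol: str
    Z: int
    A: float
    I_eV: float
    energy_grid: np.ndarray
    photoelectric: np.ndarray
    coherent: np.ndarray
    incoherent: np.ndarray

    def __post_init__(self):
        if self.Z < 1:
            raise CompositionError(f"{self.symbol}: Z must be >= 1")
        for name in ("photoelectric", "coherent", "incoherent"):
            if np.any(getattr(self, name) <= 0):
                raise CompositionError(f"{self.symbol}: non-positive {name} data")
        if np.any(np.diff(self.energy_grid) <= 0):
            raise CompositionError(f"{self.symbol}: energy grid not increasing")
        if self.energy_grid[0] > 30.0 or self.energy_grid[-1] < 150.0:
            raise CompositionError(f"{self.symbol}: grid must span 30-150 keV")

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.coherent + self.incoherent

    def mass_attenuation(self, energy_keV, partial: str = "total"):
        """Log-log cubic interpolation of a partial coefficient in energy."""
        return _element_spline(self.symbol, partial)(energy_keV)


@lru_cache(maxsize=None)
def _elements_raw() -> dict:
    with resources.files("dectspr.data").joinpath("elements_synthetic.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def elements() -> dict[str, Element]:
    raw = _elements_raw()
    grid = np.asarray(raw["energy_grid_keV"], dtype=float)
    out = {}
    for sym, rec in raw["elements"].items():
        out[sym] = Element(
            symbol=sym,
            Z=int(rec["Z"]),
            A=float(rec["A"]),
            I_eV=float(rec["I_eV"]),
            energy_grid=grid,
            photoelectric=np.asarray(rec["photoelectric"], dtype=float),
            coherent=np.asarray(rec["coherent"], dtype=float),
            incoherent=np.asarray(rec["incoherent"], dtype=float),
        )
    return out


def element(symbol: str) -> Element:
    try:
        return elements()[symbol]
    except KeyError:
        raise CompositionError(f"unknown element symbol {symbol!r}") from None


class _LogLogSpline:
    def __init__(self, grid, values):
        self._lo, self._hi = float(grid[0]), float(grid[-1])
        self._spl = CubicSpline(np.log(grid), np.log(values))

    def __call__(self, energy_keV):
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < self._lo - 1e-9) or np.any(e > self._hi + 1e-9):
            raise OutOfDomainError(
                f"energy outside tabulated grid [{self._lo}, {self._hi}] keV"
            )
        out = np.exp(self._spl(np.log(np.clip(e, self._lo, self._hi))))
        return float(out) if np.isscalar(energy_keV) else out


@lru_cache(maxsize=None)
def _element_spline(symbol: str, partial: str) -> _LogLogSpline:
    el = element(symbol)
    values = el.total if partial == "total" else getattr(el, partial)
    return _LogLogSpline(el.energy_grid, values)


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    """A mixture defined by mass density and elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    mass_fractions: Mapping[str, float]

    def __post_init__(self):
        if self.density <= 0:
            raise CompositionError(f"{self.name}: density must be positive")
        total = float(sum(self.mass_fractions.values()))
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(
                f"{self.name}: mass fractions sum to {total:.8f}, expected 1"
            )
        for sym in self.mass_fractions:
            element(sym)  # raises CompositionError if unknown

    def electron_fractions(self) -> dict[str, float]:
        """Fraction of electrons contributed by each element (lambda_i)."""
        ze = {s: w * element(s).Z / element(s).A for s, w in self.mass_fractions.items()}
        total = sum(ze.values())
        return {s: v / total for s, v in ze.items()}

    def electrons_per_gram(self) -> float:
        return N_AVOGADRO * sum(
            w * element(s).Z / element(s).A for s, w in self.mass_fractions.items()
        )


@lru_cache(maxsize=None)
def water() -> Material:
    return Material("water", 1.0, {"H": 0.111894, "O": 0.888106})


def _load_material_file(filename: str, key: str) -> dict[str, Material]:
    with resources.files("dectspr.data").joinpath(filename).open() as fh:
        raw = json.load(fh)
    return {
        name: Material(name, rec["density_g_cm3"], rec["mass_fractions"])
        for name, rec in raw[key].items()
    }


@lru_cache(maxsize=None)
def load_tissues() -> dict[str, Material]:
    """The packaged 73-tissue reference library (synthetic/nominal)."""
    return _load_material_file("tissues_synthetic.json", "tissues")


@lru_cache(maxsize=None)
def load_inserts() -> dict[str, Material]:
    """The packaged phantom-insert surrogates (synthetic/nominal)."""
    return _load_material_file("inserts_synthetic.json", "inserts")


# ---------------------------------------------------------------------------
# mixture attenuation
# ---------------------------------------------------------------------------


def mass_attenuation(material: Material, energy_keV, partial: str = "total"):
    """Mixture-rule mass attenuation coefficient, cm^2/g.

    ``sum_i w_i (mu/rho)_i(E)`` with per-element log-log cubic interpolation.
    """
    e = np.asarray(energy_keV, dtype=float)
    out = np.zeros_like(e)
    for sym, w in material.mass_fractions.items():
        out = out + w * _element_spline(sym, partial)(e)
    return float(out) if np.isscalar(energy_keV) else out


def linear_attenuation_rel_water(material: Material, energy_keV):
    """Linear attenuation relative to water at the same energy (mu/mu_w)."""
    w = water()
    num = material.density * mass_attenuation(material, energy_keV)
    den = w.density * mass_attenuation(w, energy_keV)
    return num / den


def water_per_electron_xs(energy_keV):
    """Water's total cross section per electron, cm^2/electron.

    Multiplying a water-relative attenuation by this converts it to the
    per-electron scale of the Jackson-Hawkes basis (the water electron
    density cancels between numerator and denominator of mu/mu_w).
    """
    w = water()
    return mass_attenuation(w, energy_keV) / w.electrons_per_gram()


__all__.append("water_per_electron_xs")


# ---------------------------------------------------------------------------
# Jackson-Hawkes basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JHBasis:
    """Tabulated F/G basis of the Jackson-Hawkes parametrization.

    ``F`` carries the photoelectric part of the per-electron cross section
    divided by Z^4; ``G`` carries coherent+incoherent scattering per electron
    (both cm^2/electron).  Interpolation: log-log cubic in energy, monotone
    piecewise-cubic (PCHIP) in Z on log-values.
    """

    z_nodes: np.ndarray
    energy_grid: np.ndarray
    lnF_table: np.ndarray  # (nz, ne)
    lnG_table: np.ndarray

    @property
    def z_min(self) -> float:
        return float(self.z_nodes[0])

    @property
    def z_max(self) -> float:
        return float(self.z_nodes[-1])

    def _nodes_at(self, energy_keV: float) -> tuple[np.ndarray, np.ndarray]:
        return _basis_nodes_at(self, float(energy_keV))

    def _check_z(self, z):
        if np.any(z < self.z_min - 1e-9) or np.any(z > self.z_max + 1e-9):
            raise OutOfDomainError(
                f"Zeff outside basis domain [{self.z_min}, {self.z_max}]"
            )

    def F(self, zeff, energy_keV: float):
        """F(Zeff, E) in cm^2/electron; vectorized over ``zeff``."""
        z = np.asarray(zeff, dtype=float)
        self._check_z(z)
        lnF, _ = self._nodes_at(energy_keV)
        out = np.exp(PchipInterpolator(self.z_nodes, lnF)(z))
        return float(out) if np.isscalar(zeff) else out

    def G(self, zeff, energy_keV: float):
        """G(Zeff, E) in cm^2/electron; vectorized over ``zeff``."""
        z = np.asarray(zeff, dtype=float)
        self._check_z(z)
        _, lnG = self._nodes_at(energy_keV)
        out = np.exp(PchipInterpolator(self.z_nodes, lnG)(z))
        return float(out) if np.isscalar(zeff) else out

    def per_electron(self, zeff, energy_keV: float):
        """e(Zeff, E) = Zeff^4 F + G, cm^2/electron."""
        z = np.asarray(zeff, dtype=float)
        out = z**4 * self.F(z, energy_keV) + self.G(z, energy_keV)
        return float(out) if np.isscalar(zeff) else out


@lru_cache(maxsize=64)
def _basis_nodes_at_cached(basis_id: int, energy_keV: float):
    basis = _BASIS_REGISTRY[basis_id]
    ln_e = np.log(energy_keV)
    lg = np.log(basis.energy_grid)
    lnF = np.array([CubicSpline(lg, row)(ln_e) for row in basis.lnF_table])
    lnG = np.array([CubicSpline(lg, row)(ln_e) for row in basis.lnG_table])
    return lnF, lnG


_BASIS_REGISTRY: dict[int, "JHBasis"] = {}


def _basis_nodes_at(basis: JHBasis, energy_keV: float):
    if id(basis) not in _BASIS_REGISTRY:
        _BASIS_REGISTRY[id(basis)] = basis
    lo, hi = basis.energy_grid[0], basis.energy_grid[-1]
    if not (lo - 1e-9 <= energy_keV <= hi + 1e-9):
        raise OutOfDomainError(f"energy {energy_keV} outside [{lo}, {hi}] keV")
    return _basis_nodes_at_cached(id(basis), energy_keV)


def build_jh_basis(
    z_list: Iterable[int] | None = None,
    energy_grid: Sequence[float] | None = None,
) -> JHBasis:
    """Decompose packaged per-electron cross sections into the F/G basis.

    Per element and tabulated energy: ``e(Z,E) = (mu/rho) * A / (Z * N_A)``;
    F is the photoelectric part of ``e`` divided by Z^4, G the scattering
    part.  By construction ``Z^4 F + G`` reproduces the packaged per-electron
    cross section exactly at the table nodes.
    """
    table = elements()
    if z_list is None:
        z_list = sorted(el.Z for el in table.values() if 4 <= el.Z <= 54)
    z_nodes = np.asarray(sorted(set(z_list)), dtype=float)
    by_z = {el.Z: el for el in table.values()}
    missing = [int(z) for z in z_nodes if int(z) not in by_z]
    if missing:
        raise CompositionError(f"no packaged cross sections for Z = {missing}")
    grid = (
        by_z[int(z_nodes[0])].energy_grid
        if energy_grid is None
        else np.asarray(energy_grid, dtype=float)
    )
    lnF = np.empty((len(z_nodes), len(grid)))
    lnG = np.empty_like(lnF)
    for i, z in enumerate(z_nodes):
        el = by_z[int(z)]
        conv = el.A / (el.Z * N_AVOGADRO)  # cm^2/g -> cm^2/electron
        pe = el.mass_attenuation(grid, "photoelectric") * conv
        sc = (
            el.mass_attenuation(grid, "coherent")
            + el.mass_attenuation(grid, "incoherent")
        ) * conv
        lnF[i] = np.log(pe / z**4)
        lnG[i] = np.log(sc)
    return JHBasis(z_nodes=z_nodes, energy_grid=grid, lnF_table=lnF, lnG_table=lnG)


# ---------------------------------------------------------------------------
# ground truths
# ---------------------------------------------------------------------------


def true_red(material: Material) -> float:
    """Electron density relative to water (rho_w fixed at 1 g/cm^3)."""
    w = water()
    return (
        material.density
        * material.electrons_per_gram()
        / (1.0 * w.electrons_per_gram())
    )


def true_lnI(material: Material) -> float:
    """Bragg-additivity ln I (ln eV): electron-fraction weighted mean."""
    lam = material.electron_fractions()
    return float(sum(f * np.log(element(s).I_eV) for s, f in lam.items()))


def true_ean(material: Material, exponent: float = 3.1) -> float:
    """Power-law effective atomic number over electron fractions."""
    lam = material.electron_fractions()
    s = sum(f * element(sym).Z ** exponent for sym, f in lam.items())
    return float(s ** (1.0 / exponent))


# ---------------------------------------------------------------------------
# proton stopping power
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetheConstants:
    """Kinematic and reference constants for the SPR Bethe ratio."""

    proton_energy_MeV: float = 100.0
    proton_rest_MeV: float = PROTON_REST_MEV
    two_me_c2_MeV: float = 2.0 * ELECTRON_REST_MEV
    I_water_eV: float = 78.73

    @property
    def beta_sq(self) -> float:
        gamma = 1.0 + self.proton_energy_MeV / self.proton_rest_MeV
        b2 = 1.0 - 1.0 / gamma**2
        if not 0.0 < b2 < 1.0:
            raise ValueError("proton energy yields beta^2 outside (0, 1)")
        return b2


BETHE_DEFAULT = BetheConstants()


def _bethe_bracket(i_eV, constants: BetheConstants):
    b2 = constants.beta_sq
    i_mev = np.asarray(i_eV, dtype=float) * 1e-6
    return np.log(constants.two_me_c2_MeV * b2 / ((1.0 - b2) * i_mev)) - b2


def spr_bethe(red, i_eV, constants: BetheConstants = BETHE_DEFAULT):
    """Stopping power relative to water from RED and the material I-value."""
    num = _bethe_bracket(i_eV, constants)
    den = _bethe_bracket(constants.I_water_eV, constants)
    if np.any(num <= 0) or den <= 0:
        raise ValueError("I-value too large: Bethe bracket non-positive")
    out = np.asarray(red, dtype=float) * num / den
    return float(out) if np.isscalar(red) and np.isscalar(i_eV) else out


@dataclass(frozen=True)
class YangConstants:
    """Piecewise-linear ln I(Zeff) constants (branch split at Zeff = 8.5)."""

    a1: float = 0.120
    b1: float = 3.407
    a2: float = 0.081
    b2: float = 3.514
    z_split: float = 8.5


YANG_DEFAULT = YangConstants()


def yang_lnI(zeff, constants: YangConstants = YANG_DEFAULT):
    """ln I (ln eV) from EAN; the branch boundary belongs to the upper branch."""
    z = np.asarray(zeff, dtype=float)
    out = np.where(
        z < constants.z_split,
        constants.a1 * z + constants.b1,
        constants.a2 * z + constants.b2,
    )
    return float(out) if np.isscalar(zeff) else out


def true_spr(material: Material, constants: BetheConstants = BETHE_DEFAULT) -> float:
    """Ground-truth SPR: Bragg-additivity I and true RED through Bethe."""
    return float(
        spr_bethe(true_red(material), np.exp(true_lnI(material)), constants)
    )


__all__.append("true_spr")


# ---------------------------------------------------------------------------
# CT number conversion
# ---------------------------------------------------------------------------


def hu_to_rel_atten(ct_number):
    """(CT# + 1000) / 1000; values below -1000 HU are clamped to 0."""
    hu = np.asarray(ct_number, dtype=float)
    if np.any(hu < -1000.0):
        warnings.warn("CT numbers below -1000 HU clamped to zero attenuation")
        hu = np.maximum(hu, -1000.0)
    out = (hu + 1000.0) / 1000.0
    return float(out) if np.isscalar(ct_number) else out


def rel_atten_to_hu(rel_atten):
    """Inverse of :func:`hu_to_rel_atten`."""
    out = np.asarray(rel_atten, dtype=float) * 1000.0 - 1000.0
    return float(out) if np.isscalar(rel_atten) else out
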