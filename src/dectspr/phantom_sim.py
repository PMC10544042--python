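"""Synthetic multi-insert phantom and repeated DECT acquisition simulator.

Emulates the study design around a CIRS-style electron-density phantom in two
sizes: a cylindrical body (Head: circular, Body: elliptical cross section)
of water-equivalent plastic holding tissue-surrogate inserts, imaged
repeatedly at selectable dose with paired energy channels.

Noise model
-----------
Each acquisition draws white, zero-mean Gaussian noise fields whose standard
deviation scales as ``sqrt(dose_ref / CTDIvol)``:

* VMI channels share two basis-coefficient noise fields (water-like and
  bone-like): the noise added to a VMI at energy E is
  ``n_w + n_b * g_b(E)`` with ``g_b`` the bone basis attenuation relative to
  water.  VMIs at nearby energies are therefore strongly correlated and
  low-keV VMIs are noisier, as on scanners that synthesize VMIs from one
  basis-material decomposition.
* The two native-kV surrogate channels (VMIs at fixed effective energies,
  56 / 89 keV by default) carry *independent* per-channel noise fields,
  emulating the independent quantum noise of two separate tube/detector
  measurements on a dual-source scanner.

Noise-free acquisitions reproduce the ground-truth HU exactly.  A
strength-parameterized Gaussian smoothing stands in for the scanners'
iterative / deep-learning noise reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from . import physics_core as pc

__all__ = [
    "PhantomSpecError",
    "InsertSpec",
    "PhantomSpec",
    "Phantom",
    "NoiseModel",
    "AcquisitionSpec",
    "head_spec",
    "body_spec",
    "build_phantom",
    "ground_truth_maps",
    "simulate_acquisition",
    "apply_noise_reduction",
    "NOISE_REDUCTION_SIGMAS",
    "KV_LOW",
    "KV_HIGH",
]

KV_LOW = "kv_low"
KV_HIGH = "kv_high"

# noise-reduction surrogate: level -> Gaussian kernel sigma in voxels
NOISE_REDUCTION_SIGMAS = {0: 0.0, 1: 0.5, 2: 1.0, 3: 1.5}


class PhantomSpecError(ValueError):
    """The phantom specification is geometrically or materially invalid."""


@dataclass(frozen=True)
class InsertSpec:
    material: str          # key into the packaged insert table
    center_mm: tuple[float, float]  # in-plane (x, y) relative to phantom axis
    diameter_mm: float = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical phantom: elliptical cross section, axis along z."""

    name: str
    radii_mm: tuple[float, float]      # (rx, ry); equal for the Head phantom
    height_mm: float
    inserts: tuple[InsertSpec, ...]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    body_material: str = "water"
    margin_mm: float = 8.0             # background rim around the body


def _ring_inserts(ring_radius: float, materials: Sequence[str]) -> tuple[InsertSpec, ...]:
    out = [InsertSpec("water", (0.0, 0.0))]
    for i, mat in enumerate(materials):
        ang = 2.0 * math.pi * i / len(materials)
        out.append(
            InsertSpec(mat, (ring_radius * math.cos(ang), ring_radius * math.sin(ang)))
        )
    return tuple(out)


_RING_MATERIALS = (
    "lung_inhale", "lung_exhale", "adipose", "breast",
    "muscle", "liver", "bone_200", "bone_800",
)


def head_spec(height_mm: float = 60.0) -> PhantomSpec:
    """Head-size phantom: 180 mm circular cross section, 8-insert ring + center."""
    return PhantomSpec(
        name="Head", radii_mm=(90.0, 90.0), height_mm=height_mm,
        inserts=_ring_inserts(55.0, _RING_MATERIALS),
    )


def body_spec(height_mm: float = 60.0) -> PhantomSpec:
    """Body-size phantom: 330 x 270 mm elliptical cross section."""
    return PhantomSpec(
        name="Body", radii_mm=(165.0, 135.0), height_mm=height_mm,
        inserts=_ring_inserts(100.0, _RING_MATERIALS),
    )


@dataclass(frozen=True)
class Phantom:
    """Voxelized phantom: label volume plus the material behind each label.

    Label 0 is background (no material); label 1 the body; labels 2+ the
    inserts in spec order.
    """

    spec: PhantomSpec
    labels: np.ndarray               # (nx, ny, nz) int16
    materials: tuple                 # index -> Material | None (label 0)
    origin_mm: tuple[float, float]   # in-plane coordinate of voxel (0, 0) center

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.spec.spacing_mm

    def insert_center_mm(self, material_name: str) -> tuple[float, float]:
        for ins in self.spec.inserts:
            if ins.material == material_name:
                return ins.center_mm
        raise KeyError(material_name)

    def voxel_centers(self):
        dx, dy, _ = self.spacing_mm
        nx, ny = self.labels.shape[:2]
        x = self.origin_mm[0] + dx * np.arange(nx)
        y = self.origin_mm[1] + dy * np.arange(ny)
        return x, y


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the phantom: voxels take the material of their center."""
    inserts = spec.inserts
    rx, ry = spec.radii_mm
    for i, ins in enumerate(inserts):
        cx, cy = ins.center_mm
        r = ins.diameter_mm / 2.0
        # inside the body ellipse with the full insert radius
        scale = math.hypot(cx / rx, cy / ry)
        if scale + r / min(rx, ry) > 1.0:
            raise PhantomSpecError(f"insert {ins.material!r} extends outside the body")
        for other in inserts[i + 1 :]:
            d = math.dist(ins.center_mm, other.center_mm)
            if d < r + other.diameter_mm / 2.0:
                raise PhantomSpecError(
                    f"inserts {ins.material!r} and {other.material!r} overlap"
                )

    dx, dy, dz = spec.spacing_mm
    nx = int(round(2 * (rx + spec.margin_mm) / dx))
    ny = int(round(2 * (ry + spec.margin_mm) / dy))
    nz = max(1, int(round(spec.height_mm / dz)))
    x0 = -(nx - 1) / 2.0 * dx
    y0 = -(ny - 1) / 2.0 * dy
    x = x0 + dx * np.arange(nx)
    y = y0 + dy * np.arange(ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")

    labels2d = np.zeros((nx, ny), dtype=np.int16)
    labels2d[(xx / rx) ** 2 + (yy / ry) ** 2 <= 1.0] = 1
    insert_table = pc.load_inserts()
    materials: list = [None]
    body = (
        pc.water()
        if spec.body_material == "water"
        else insert_table[spec.body_material]
    )
    materials.append(body)
    for idx, ins in enumerate(inserts, start=2):
        if ins.material not in insert_table and ins.material != "water":
            raise PhantomSpecError(f"unknown insert material {ins.material!r}")
        mat = pc.water() if ins.material == "water" else insert_table[ins.material]
        cx, cy = ins.center_mm
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (ins.diameter_mm / 2.0) ** 2
        labels2d[mask] = idx
        materials.append(mat)
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    return Phantom(spec=spec, labels=labels, materials=tuple(materials), origin_mm=(x0, y0))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _label_lookup(phantom: Phantom, values: Sequence[float]) -> np.ndarray:
    table = np.asarray(values, dtype=float)
    return table[phantom.labels]


def ground_truth_maps(phantom: Phantom) -> dict[str, np.ndarray]:
    """Noise-free SPR / RED / EAN maps by label lookup (background = 0/NaN)."""
    spr = [0.0] + [pc.true_spr(m) for m in phantom.materials[1:]]
    red = [0.0] + [pc.true_red(m) for m in phantom.materials[1:]]
    ean = [np.nan] + [pc.true_ean(m) for m in phantom.materials[1:]]
    return {
        "SPR": _label_lookup(phantom, spr),
        "RED": _label_lookup(phantom, red),
        "EAN": _label_lookup(phantom, ean),
    }


def ground_truth_rel_atten(phantom: Phantom, energy_keV: float) -> np.ndarray:
    """Noise-free mu/mu_w volume at one energy (background = 0)."""
    vals = [0.0] + [
        pc.linear_attenuation_rel_water(m, energy_keV) for m in phantom.materials[1:]
    ]
    return _label_lookup(phantom, vals)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Two-basis VMI noise plus independent native-channel noise.

    Standard deviations are in water-relative attenuation units at the
    reference dose (1 unit = 1000 HU); dose scaling follows the inverse
    square root law.
    """

    sigma_basis_water: float = 0.009
    sigma_basis_bone: float = 0.004
    sigma_kv_low: float = 0.020
    sigma_kv_high: float = 0.014
    dose_ref_mGy: float = 10.0
    kv_low_keV: float = 56.0
    kv_high_keV: float = 89.0
    bone_basis_material: str = "cortical_bone"  # packaged tissue

    def dose_scale(self, ctdivol_mGy: float) -> float:
        if ctdivol_mGy <= 0:
            raise ValueError("CTDIvol must be positive")
        return math.sqrt(self.dose_ref_mGy / ctdivol_mGy)


@lru_cache(maxsize=None)
def _bone_basis_rel_atten(material_name: str, energy_keV: float) -> float:
    mat = pc.load_tissues()[material_name]
    return float(pc.linear_attenuation_rel_water(mat, energy_keV))


@dataclass(frozen=True)
class AcquisitionSpec:
    """One imaging condition: dose, channels, noise reduction, repeats."""

    ctdivol_mGy: float = 10.0
    vmi_keV: tuple[float, ...] = ()
    include_native: bool = True
    noise_reduction: int = 0
    repeats: int = 30
    base_seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if self.ctdivol_mGy <= 0:
            raise ValueError("CTDIvol must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.noise_reduction not in NOISE_REDUCTION_SIGMAS:
            raise ValueError(
                f"unknown noise-reduction level {self.noise_reduction}; "
                f"configured: {sorted(NOISE_REDUCTION_SIGMAS)}"
            )

    def channels(self) -> list:
        out: list = list(self.vmi_keV)
        if self.include_native:
            out += [KV_LOW, KV_HIGH]
        return out


def simulate_acquisition(
    phantom: Phantom, acq: AcquisitionSpec, repeat_index: int
) -> dict:
    """One noisy acquisition: channel key -> HU volume.

    Channel keys are VMI energies (float keV) and/or ``"kv_low"``/
    ``"kv_high"``.  Deterministic given ``(base_seed, repeat_index)``; the
    four noise fields are always drawn in a fixed order so the realization
    does not depend on which channels are requested.
    """
    if repeat_index < 0:
        raise ValueError("repeat_index must be >= 0")
    noise = acq.noise
    grid_lo, grid_hi = 40.0, 140.0
    for e in acq.vmi_keV:
        if not grid_lo <= e <= grid_hi:
            raise ValueError(f"VMI energy {e} keV outside basis range [40, 140]")

    rng = np.random.default_rng([int(acq.base_seed), int(repeat_index)])
    shape = phantom.labels.shape
    n_w = rng.standard_normal(shape)
    n_b = rng.standard_normal(shape)
    n_low = rng.standard_normal(shape)
    n_high = rng.standard_normal(shape)
    scale = noise.dose_scale(acq.ctdivol_mGy)

    out = {}
    for e in acq.vmi_keV:
        truth = ground_truth_rel_atten(phantom, e)
        gb = _bone_basis_rel_atten(noise.bone_basis_material, float(e))
        rel = truth + scale * (
            noise.sigma_basis_water * n_w + noise.sigma_basis_bone * gb * n_b
        )
        out[float(e)] = pc.rel_atten_to_hu(rel)
    if acq.include_native:
        truth_l = ground_truth_rel_atten(phantom, noise.kv_low_keV)
        truth_h = ground_truth_rel_atten(phantom, noise.kv_high_keV)
        out[KV_LOW] = pc.rel_atten_to_hu(truth_l + scale * noise.sigma_kv_low * n_low)
        out[KV_HIGH] = pc.rel_atten_to_hu(truth_h + scale * noise.sigma_kv_high * n_high)
    if acq.noise_reduction:
        out = {k: apply_noise_reduction(v, acq.noise_reduction) for k, v in out.items()}
    return out


def apply_noise_reduction(volume: np.ndarray, level: int) -> np.ndarray:
    """Strength-parameterized smoothing surrogate for iterative reconstruction.

    Gaussian kernel width grows with level; level 0 is the identity.  ROI
    means are preserved (up to boundary effects of the nearest-edge padding).
    """
    if level not in NOISE_REDUCTION_SIGMAS:
        raise ValueError(f"unknown noise-reduction level {level}")
    sigma = NOISE_REDUCTION_SIGMAS[level]
    if sigma == 0.0:
        return np.array(volume, copy=True)
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma, mode="nearest")
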