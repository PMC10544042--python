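"""Landry-Saito SPR mapping from native low/high-kV CT numbers.

The effective atomic number is tied to the CT-number ratio of the two native
images through the rational model

    (CT#low/1000 + 1) / (CT#high/1000 + 1) = (1 + A z) / (B + C z),
    z = Zeff^(m-1),

and the relative electron density to the weighted CT-number difference

    rho_e = a [ (1+alpha) CT#high - alpha CT#low ] / 1000 + b.

Both are calibrated by least squares on phantom inserts with known EAN and
RED.  Because inverting the ratio model voxel-wise produces unphysical
(negative) ``z`` for a sizeable fraction of noisy voxels, the per-voxel
EAN -> I step is bypassed: a clamped monotone lookup maps ``z`` directly to
ln I, fitted through the reference-tissue library.  SPR then follows from the
Bethe ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.isotonic import IsotonicRegression

from .physics_core import (
    BETHE_DEFAULT,
    BetheConstants,
    Material,
    spr_bethe,
    true_ean,
    true_lnI,
    true_red,
)

__all__ = [
    "FitError",
    "LSCalibration",
    "LnILookup",
    "calibrate_ls",
    "build_lnI_lut",
    "red_ls",
    "map_spr_ls",
    "forward_ct_numbers_ls",
]


class FitError(ValueError):
    """The calibration design is degenerate or the fit failed."""


@dataclass(frozen=True)
class LSCalibration:
    """Fitted constants of the ratio (A, B, C, m) and RED (alpha, a, b) models."""

    A: float
    B: float
    C: float
    m: float
    alpha: float
    a: float
    b: float
    ratio_rms_residual: float = 0.0
    red_rms_residual: float = 0.0
    phantom_id: str = ""

    def __post_init__(self):
        if self.m <= 1.0:
            raise FitError(f"exponent m must exceed 1, got {self.m}")


@dataclass(frozen=True)
class LnILookup:
    """Clamped monotone piecewise-linear map from z = Zeff^(m-1) to ln I."""

    x_breakpoints: np.ndarray
    lnI_values: np.ndarray
    m: float

    def __post_init__(self):
        x = np.asarray(self.x_breakpoints, dtype=float)
        if x.ndim != 1 or len(x) < 2 or np.any(np.diff(x) <= 0):
            raise FitError("lookup breakpoints must be strictly increasing")
        if np.any(np.diff(np.asarray(self.lnI_values, dtype=float)) < 0):
            raise FitError("lookup values must be non-decreasing")

    def __call__(self, x):
        """Total, clamped evaluation: any real x maps into the fitted range."""
        out = np.interp(np.asarray(x, dtype=float), self.x_breakpoints, self.lnI_values)
        return float(out) if np.isscalar(x) else out


def _ratio_model(z, A, B, C):
    return (1.0 + A * z) / (B + C * z)


def _check_design(materials: Sequence[Material], minimum: int):
    if len(materials) < minimum:
        raise FitError(f"need at least {minimum} calibration inserts, got {len(materials)}")
    ean = np.array([true_ean(m, 3.1) for m in materials])
    if np.ptp(ean) < 0.1:
        raise FitError("degenerate design: calibration inserts share one EAN")


def calibrate_ls(
    ct_low: Sequence[float],
    ct_high: Sequence[float],
    materials: Sequence[Material],
    *,
    phantom_id: str = "",
    m_starts: Sequence[float] = (3.0, 3.3, 3.6),
) -> LSCalibration:
    """Least-squares calibration of both models on phantom-insert CT numbers.

    The ratio model is fitted in (A, B, C, m) with multi-start over the
    exponent; within each residual evaluation the insert EAN truth is the
    exponent-m power-law mean, so truth and model stay consistent.  The RED
    model is linear in a reparametrization and solved exactly.
    """
    ct_low = np.asarray(ct_low, dtype=float)
    ct_high = np.asarray(ct_high, dtype=float)
    _check_design(materials, 5)
    r = (ct_low / 1000.0 + 1.0) / (ct_high / 1000.0 + 1.0)

    def residuals(params):
        A, B, C, m = params
        z = np.array([true_ean(mat, m) ** (m - 1.0) for mat in materials])
        return r - _ratio_model(z, A, B, C)

    best = None
    for m0 in m_starts:
        try:
            fit = optimize.least_squares(
                residuals,
                x0=[0.05, 1.0, 0.02, m0],
                bounds=([-1.0, 1e-3, -1.0, 1.5], [1.0, 10.0, 1.0, 6.0]),
                xtol=1e-14,
                ftol=1e-14,
            )
        except Exception:  # singular jacobian on degenerate designs
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise FitError("ratio-model fit failed for all starting exponents")
    A, B, C, m = best.x
    ratio_rms = float(np.sqrt(np.mean(best.fun**2)))

    # RED model: rho_e = p*CT#high + q*CT#low + b is linear; map back to
    # (alpha, a, b) via p = a(1+alpha)/1000, q = -a*alpha/1000.
    red_truth = np.array([true_red(mat) for mat in materials])
    design = np.column_stack([ct_high, ct_low, np.ones_like(ct_low)])
    coef, *_ = np.linalg.lstsq(design, red_truth, rcond=None)
    p, q, b = coef
    a = 1000.0 * (p + q)
    if abs(a) < 1e-12:
        raise FitError("degenerate RED fit: vanishing slope")
    alpha = -1000.0 * q / a
    red_rms = float(np.sqrt(np.mean((design @ coef - red_truth) ** 2)))

    return LSCalibration(
        A=float(A), B=float(B), C=float(C), m=float(m),
        alpha=float(alpha), a=float(a), b=float(b),
        ratio_rms_residual=ratio_rms, red_rms_residual=red_rms,
        phantom_id=phantom_id,
    )


def build_lnI_lut(tissues: Sequence[Material], m: float) -> LnILookup:
    """Monotone ln I lookup fitted through the reference-tissue cloud.

    Isotonic regression of Bragg-additivity ln I against z = EAN^(m-1)
    guarantees a monotone, total (clamped) piecewise-linear map; unphysical
    (e.g. negative) query values fall back to the lookup minimum.
    """
    if len(tissues) < 3:
        raise FitError("need at least 3 tissues to build the ln I lookup")
    x = np.array([true_ean(t, m) ** (m - 1.0) for t in tissues])
    y = np.array([true_lnI(t) for t in tissues])
    order = np.argsort(x)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(x[order], y[order])
    # collapse ties introduced by the isotonic pooling into unique breakpoints
    xs, idx = np.unique(x[order], return_index=True)
    ys = fitted[idx]
    keep = np.concatenate([[True], np.diff(xs) > 1e-12])
    return LnILookup(x_breakpoints=xs[keep], lnI_values=ys[keep], m=float(m))


def red_ls(ct_low, ct_high, calib: LSCalibration):
    """Relative electron density from the weighted CT-number difference."""
    h = np.asarray(ct_high, dtype=float)
    low = np.asarray(ct_low, dtype=float)
    out = calib.a * ((1.0 + calib.alpha) * h - calib.alpha * low) / 1000.0 + calib.b
    return float(out) if np.isscalar(ct_low) and np.isscalar(ct_high) else out


def invert_ratio_for_z(ct_low, ct_high, calib: LSCalibration):
    """Closed-form z = Zeff^(m-1) from the CT-number ratio (may be unphysical)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (np.asarray(ct_low, dtype=float) / 1000.0 + 1.0) / (
            np.asarray(ct_high, dtype=float) / 1000.0 + 1.0
        )
        return (r * calib.B - 1.0) / (calib.A - r * calib.C)


def map_spr_ls(
    ct_low_vol: np.ndarray,
    ct_high_vol: np.ndarray,
    calib: LSCalibration,
    lut: LnILookup,
    constants: BetheConstants = BETHE_DEFAULT,
) -> dict[str, np.ndarray]:
    """Voxel-wise RED and SPR maps; the per-voxel EAN step is bypassed.

    ln I comes from the clamped lookup at the closed-form z, so noisy voxels
    with unphysical z still yield finite SPR.  No EAN volume is produced.
    """
    low = np.asarray(ct_low_vol, dtype=float)
    high = np.asarray(ct_high_vol, dtype=float)
    if low.shape != high.shape:
        raise ValueError(f"grid mismatch: {low.shape} vs {high.shape}")
    z = invert_ratio_for_z(low, high, calib)
    z = np.where(np.isfinite(z), z, lut.x_breakpoints[0])
    ln_i = lut(z)
    red = red_ls(low, high, calib)
    spr = np.where(red > 0, red, 0.0) * _bethe_factor(np.exp(ln_i), constants)
    return {"RED": red, "SPR": spr}


def _bethe_factor(i_eV, constants: BetheConstants):
    b2 = constants.beta_sq
    num = np.log(constants.two_me_c2_MeV * b2 / ((1 - b2) * np.asarray(i_eV) * 1e-6)) - b2
    den = np.log(constants.two_me_c2_MeV * b2 / ((1 - b2) * constants.I_water_eV * 1e-6)) - b2
    return num / den


def forward_ct_numbers_ls(
    materials: Sequence[Material], params: LSCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Exact forward generator: CT numbers consistent with both models.

    For each material, solves the two model equations for (CT#low, CT#high)
    given its true EAN (exponent m) and RED.  Used for closed-loop
    calibration-recovery checks.
    """
    lows, highs = [], []
    for mat in materials:
        z = true_ean(mat, params.m) ** (params.m - 1.0)
        r = _ratio_model(z, params.A, params.B, params.C)
        rho = true_red(mat)
        # h = CT#high/1000 + 1 from the RED model with l = r*h
        h = ((rho - params.b) / params.a + 1.0) / (1.0 + params.alpha - params.alpha * r)
        l = r * h
        highs.append((h - 1.0) * 1000.0)
        lows.append((l - 1.0) * 1000.0)
    return np.asarray(lows), np.asarray(highs)
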