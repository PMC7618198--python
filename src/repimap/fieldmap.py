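"""dB0 field-map estimation from multi-echo image phase.

The off-resonance field follows from the phase evolution between echo
images acquired at different echo times:

    dB0(r) = dPhi(r) / (2 pi dTE)

with dPhi the (unwrapped) phase difference.  For three echoes with
equal spacing the two pairwise differences are averaged, halving the
phase noise variance.  The short dTE of a blip-rewound EPI readout
keeps |dPhi| well below pi for physiological field offsets, so the
estimate is essentially wrap-free; the long dTE of sequential
multi-echo EPI wraps many times over and leaves a residual global
2*pi*k ambiguity that no single-readout estimator can resolve.

Processing chain of :func:`estimate_b0`: wrapped pairwise differences
-> (3-echo) phasor-mean averaging -> 2-D phase unwrapping -> 4th-order
polynomial smoothing/extrapolation -> conversion to Hz.  EPI-derived
field maps live in the *distorted* image space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .recon import EchoImages

__all__ = [
    "PhaseEvolutionMap",
    "FieldMap",
    "wrapped_diff",
    "mean_evolution",
    "unwrap2d",
    "polyfit_extrapolate",
    "to_hz",
    "estimate_b0",
]


@dataclass
class PhaseEvolutionMap:
    """Phase evolution dPhi (rad) over an echo-time gap of ``dte_ms``."""

    dphi_rad: np.ndarray
    mask: np.ndarray
    dte_ms: float
    wrapped: bool = True
    weight: np.ndarray | None = None  # magnitude weight for fitting


@dataclass
class FieldMap:
    """Off-resonance map in Hz with a validity mask.

    ``space_tag`` records whether the map lives in the distorted (EPI)
    or undistorted (ground-truth/GRE-like) image geometry.
    """

    b0_hz: np.ndarray
    mask: np.ndarray
    space_tag: str = "distorted"


def wrapped_diff(
    echo_a: np.ndarray,
    echo_b: np.ndarray,
    dte_ms: float,
    mask_fraction: float = 0.05,
) -> PhaseEvolutionMap:
    """Wrapped phase difference arg(echo_b * conj(echo_a)) in (-pi, pi].

    The validity mask keeps pixels where both echo magnitudes exceed
    ``mask_fraction`` of the robust (99th percentile) maximum.
    """
    echo_a = np.asarray(echo_a)
    echo_b = np.asarray(echo_b)
    if echo_a.shape != echo_b.shape:
        raise ValueError("echo images must share a shape")
    prod = echo_b * np.conj(echo_a)
    dphi = np.angle(prod)
    mag_a, mag_b = np.abs(echo_a), np.abs(echo_b)
    robust_max = max(np.percentile(mag_a, 99), np.percentile(mag_b, 99))
    mask = (mag_a > mask_fraction * robust_max) & (mag_b > mask_fraction * robust_max)
    return PhaseEvolutionMap(
        dphi_rad=dphi, mask=mask, dte_ms=dte_ms, wrapped=True, weight=np.abs(prod)
    )


def mean_evolution(
    d12: PhaseEvolutionMap, d23: PhaseEvolutionMap, literal: bool = False
) -> PhaseEvolutionMap:
    """Average the echo-1/2 and echo-2/3 phase evolutions.

    The default phasor mean ``arg(exp(i d12) + exp(i d23))`` equals the
    arithmetic mean wherever ``|d12 - d23| < pi`` (guaranteed in the
    short-dTE regime) but is free of the seam discontinuity the literal
    arithmetic mean of wrapped values exhibits near +/-pi.  Set
    ``literal=True`` for the plain arithmetic mean.
    """
    if not np.isclose(d12.dte_ms, d23.dte_ms):
        raise ValueError(
            f"echo-time gaps differ: {d12.dte_ms} vs {d23.dte_ms} ms"
        )
    if literal:
        mean = 0.5 * (d12.dphi_rad + d23.dphi_rad)
    else:
        mean = np.angle(np.exp(1j * d12.dphi_rad) + np.exp(1j * d23.dphi_rad))
    w = None
    if d12.weight is not None and d23.weight is not None:
        w = 0.5 * (d12.weight + d23.weight)
    return PhaseEvolutionMap(
        dphi_rad=mean,
        mask=d12.mask & d23.mask,
        dte_ms=d12.dte_ms,
        wrapped=True,
        weight=w,
    )


def unwrap2d(
    phase: PhaseEvolutionMap, mask: np.ndarray | None = None
) -> PhaseEvolutionMap:
    """2-D phase unwrapping inside the mask.

    Backed by the reliability-sorted unwrapper of scikit-image; each
    connected mask component is unwrapped independently and anchored by
    an integer multiple of 2*pi so its median lies in (-pi, pi].  The
    output equals the input modulo 2*pi at every masked pixel (exactly);
    no relationship between disconnected components is claimed.
    """
    mask = phase.mask if mask is None else mask
    if not np.any(mask):
        raise ValueError("empty mask")
    out = np.array(phase.dphi_rad, dtype=float, copy=True)
    labels, n_comp = ndimage.label(mask)
    for comp in range(1, n_comp + 1):
        sel = labels == comp
        ma = np.ma.array(phase.dphi_rad, mask=~sel)
        uw = _skimage_unwrap(ma)
        vals = np.asarray(uw[sel])
        med = np.median(vals)
        k = np.floor((med + np.pi) / (2 * np.pi))  # anchor median into (-pi, pi]
        out[sel] = vals - 2 * np.pi * k
    return PhaseEvolutionMap(
        dphi_rad=out, mask=mask, dte_ms=phase.dte_ms, wrapped=False, weight=phase.weight
    )


def _poly_basis(shape: tuple[int, int], order: int) -> np.ndarray:
    n1, n2 = shape
    y = (np.arange(n1) - (n1 - 1) / 2) / (n1 / 2)
    x = (np.arange(n2) - (n2 - 1) / 2) / (n2 / 2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [
        (yy**i) * (xx**j)
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.stack(cols, axis=-1)  # (n1, n2, n_coef)


def polyfit_extrapolate(
    phase: PhaseEvolutionMap,
    mask: np.ndarray | None = None,
    order: int = 4,
) -> tuple[PhaseEvolutionMap, np.ndarray]:
    """Magnitude-weighted 2-D polynomial fit of total degree <= order.

    Returns the fit evaluated on the full grid (extrapolating outside
    the mask) and the residual map (zero outside the mask).  Raises if
    the masked pixels cannot determine the coefficients (fewer than
    twice their count, or degenerate mask geometry).
    """
    mask = phase.mask if mask is None else mask
    basis = _poly_basis(phase.dphi_rad.shape, order)
    n_coef = basis.shape[-1]
    idx = np.flatnonzero(mask)
    if idx.size < 2 * n_coef:
        raise ValueError(
            f"only {idx.size} masked pixels for {n_coef} coefficients"
        )
    A = basis.reshape(-1, n_coef)[idx]
    b = phase.dphi_rad.reshape(-1)[idx]
    if phase.weight is not None:
        # weight residuals by the echo-product magnitude: low-magnitude
        # pixels carry not just higher phase noise but structured
        # reconstruction artifacts, so they are suppressed quadratically
        w = phase.weight.reshape(-1)[idx]
        A = A * w[:, None]
        b = b * w
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n_coef:
        raise ValueError("rank-deficient polynomial basis on this mask")
    fit = basis @ coef
    residual = np.where(mask, phase.dphi_rad - fit, 0.0)
    return (
        PhaseEvolutionMap(
            dphi_rad=fit, mask=mask, dte_ms=phase.dte_ms, wrapped=False,
            weight=phase.weight,
        ),
        residual,
    )


def to_hz(phase: PhaseEvolutionMap) -> FieldMap:
    """Convert an unwrapped phase-evolution map to Hz.

    ``b0_hz = dphi / (2 pi dTE)``; EPI-derived maps are tagged as
    living in the distorted space.
    """
    if phase.dte_ms <= 0:
        raise ValueError("dTE must be positive")
    if phase.wrapped:
        raise ValueError("phase must be unwrapped before conversion to Hz")
    b0 = phase.dphi_rad / (2 * np.pi * phase.dte_ms * 1e-3)
    return FieldMap(b0_hz=b0, mask=phase.mask, space_tag="distorted")


def estimate_b0(
    echo_images: EchoImages,
    mask_fraction: float = 0.05,
    smoothing: str = "fit",
    order: int = 4,
) -> FieldMap:
    """Estimate a dB0 map from 2- or 3-echo complex images.

    For three echoes the two pairwise evolutions are averaged (phasor
    mean) before unwrapping; for two echoes the single difference is
    used.  ``smoothing``:

    * ``"fit"`` (default) -- replace the unwrapped phase by its
      4th-order polynomial fit, extrapolated over the full grid.  This
      mirrors the behaviour of polynomial field-map regularization in
      standard EPI-unwarping tools and is the right choice when the
      underlying field is smooth.
    * ``"fit_plus_residual"`` -- keep the masked residual on top of the
      fit (preserves localized structure the polynomial cannot express,
      at the price of retaining per-pixel phase noise).
    * ``"none"`` -- unwrapped phase only.
    """
    imgs = echo_images.data
    ne = imgs.shape[0]
    if ne not in (2, 3):
        raise ValueError("field mapping needs 2 or 3 echoes")
    tes = echo_images.te_ms
    gaps = np.diff(tes)
    if ne == 3:
        if not np.isclose(gaps[0], gaps[1]):
            raise ValueError("3-echo estimation requires equally spaced TEs")
        d12 = wrapped_diff(imgs[0], imgs[1], gaps[0], mask_fraction)
        d23 = wrapped_diff(imgs[1], imgs[2], gaps[1], mask_fraction)
        pem = mean_evolution(d12, d23)
    else:
        pem = wrapped_diff(imgs[0], imgs[1], gaps[0], mask_fraction)

    uw = unwrap2d(pem)
    if smoothing == "none":
        return to_hz(uw)
    fit, residual = polyfit_extrapolate(uw, order=order)
    # a smoothing fit must not exceed the range the reliable data show:
    # clamp to the phase range of the well-weighted pixels (with a 25%
    # margin) so low-weight border regions cannot drag the polynomial
    # beyond anything observed
    if uw.weight is not None:
        reliable = uw.mask & (uw.weight > 0.05 * uw.weight[uw.mask].max())
    else:
        reliable = uw.mask
    lo = float(uw.dphi_rad[reliable].min())
    hi = float(uw.dphi_rad[reliable].max())
    span = max(hi - lo, 1e-9)
    fit.dphi_rad = np.clip(fit.dphi_rad, lo - 0.25 * span, hi + 0.25 * span)
    if smoothing == "fit_plus_residual":
        fit = PhaseEvolutionMap(
            dphi_rad=fit.dphi_rad + residual, mask=fit.mask,
            dte_ms=fit.dte_ms, wrapped=False, weight=fit.weight,
        )
    elif smoothing != "fit":
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    out = to_hz(fit)
    # a degree-4 polynomial explodes when extrapolated to the FOV
    # corners; outside the mask the field is taken from the nearest
    # masked pixel (lightly smoothed), which keeps the shift map bounded
    # and fold-over free while preserving the fit inside the object
    idx = ndimage.distance_transform_edt(
        ~out.mask, return_distances=False, return_indices=True
    )
    filled = np.where(out.mask, out.b0_hz, out.b0_hz[tuple(idx)])
    smoothed = ndimage.gaussian_filter(filled, 2.0)
    out.b0_hz = np.where(out.mask, out.b0_hz, smoothed)
    return out
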