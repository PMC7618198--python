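"""Synthetic multi-coil EPI scanner.

Generates digital phantoms, smooth complex coil sensitivities and
ground-truth off-resonance (dB0) fields, and acquires multi-coil k-space
along any :class:`~repimap.trajectory.Trajectory` with per-line
off-resonance phase evolution.  Because each readout line is acquired at
a different time, a nonzero dB0 field produces geometric distortion
along the phase-encode axis *physically* -- no explicit warp is applied
-- so the simulator can cross-validate the image-domain distortion model
in :mod:`repimap.unwarp`.

Off-resonance is applied per trajectory line (piecewise-constant over
each readout line), not per ADC sample within a line: at EPI bandwidths
the readout-direction distortion is negligible and only the
phase-encode-direction distortion is modelled, which is the standard EPI
distortion model.

Axis convention: axis 0 is readout (N1), axis 1 is phase encode (N2).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fourier import fft2c
from .trajectory import Trajectory

__all__ = [
    "PhantomImage",
    "SensitivityMaps",
    "GroundTruthField",
    "MotionSchedule",
    "KspaceData",
    "make_phantom",
    "make_coils",
    "make_field",
    "acquire",
    "simulate_series",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PhantomImage:
    """Digital ellipse-composite phantom.

    ``magnitude`` is zero outside ``support_mask``; ``label_map`` assigns
    an integer tissue class per pixel (0 = background).
    """

    magnitude: np.ndarray
    label_map: np.ndarray
    support_mask: np.ndarray


@dataclass
class SensitivityMaps:
    """Complex per-coil spatial sensitivity maps, (n_coils, n1, n2).

    Normalized so the coil sum-of-squares is 1 everywhere.
    """

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class GroundTruthField:
    """Ground-truth dB0 map in Hz with its named generative parts."""

    b0_hz: np.ndarray
    components: dict = dc_field(default_factory=dict)


@dataclass
class MotionSchedule:
    """Per-volume rigid pose and pose-dependent field perturbation.

    ``poses`` is a list of (rotation_deg, shift_readout_mm, shift_pe_mm)
    tuples, one per volume; volume 0 must be the identity pose.  The
    pose-dependent field change is modelled as a linear in-plane gradient
    scaled by the rotation angle (``field_gain_hz_per_deg`` Hz per degree
    peak-to-center at the field-of-view edge), on top of rigid transport
    of the base field.  This is a synthetic stand-in: real
    susceptibility-field changes under head rotation are not modelled
    quantitatively anywhere, only their existence and smoothness.
    """

    poses: list[tuple[float, float, float]]
    field_gain_hz_per_deg: float = 1.0

    def __post_init__(self) -> None:
        if len(self.poses) == 0:
            raise ValueError("empty schedule")
        if tuple(self.poses[0]) != (0.0, 0.0, 0.0):
            raise ValueError("volume 0 must have the identity pose")

    @property
    def n_volumes(self) -> int:
        return len(self.poses)

    def transition_volumes(self) -> list[int]:
        """Indices of volumes whose pose differs from the previous one."""
        return [
            v
            for v in range(1, self.n_volumes)
            if tuple(self.poses[v]) != tuple(self.poses[v - 1])
        ]


@dataclass
class KspaceData:
    """Multi-coil samples acquired along a trajectory.

    ``samples`` has shape (n_lines, n_coils, n_readout): one fully
    sampled readout line per trajectory entry.
    """

    samples: np.ndarray
    traj: Trajectory
    noise_sigma: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]

    def to_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Assemble per-echo Cartesian k-space and sampling masks.

        Returns ``(kspace, masks)`` with ``kspace`` of shape
        (n_echoes, n_coils, n_readout, n_pe), zero at unacquired lines,
        and ``masks`` boolean (n_echoes, n_pe).
        """
        tr = self.traj
        n1 = self.samples.shape[2]
        grid = np.zeros((tr.n_echoes, self.n_coils, n1, tr.n_pe), dtype=complex)
        masks = np.zeros((tr.n_echoes, tr.n_pe), dtype=bool)
        for i, ln in enumerate(tr.lines):
            grid[ln.echo, :, :, ln.ky] = self.samples[i]
            masks[ln.echo, ln.ky] = True
        return grid, masks


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _ellipse(n1, n2, cx, cy, ax_, ay, angle_deg=0.0):
    y, x = np.mgrid[0:n1, 0:n2]
    x = (x - cy) / ay
    yy = (y - cx) / ax_
    th = np.deg2rad(angle_deg)
    u = np.cos(th) * yy + np.sin(th) * x
    v = -np.sin(th) * yy + np.cos(th) * x
    return u**2 + v**2 <= 1.0


def make_phantom(n1: int, n2: int, seed: int = 0) -> PhantomImage:
    """Ellipse-composite digital phantom with >= 3 tissue classes.

    The outer shell occupies at least 40% of the field of view; internal
    structures (ventricle-like dark ellipse, two bright nodules) get
    distinct labels and magnitudes.  Deterministic given ``seed``.
    """
    if n1 < 16 or n2 < 16:
        raise ValueError("phantom grid must be at least 16x16")
    rng = np.random.default_rng(seed)
    jit = lambda s: 1.0 + s * (rng.random() - 0.5)

    label = np.zeros((n1, n2), dtype=int)
    mag = np.zeros((n1, n2), dtype=float)

    shell = _ellipse(n1, n2, n1 / 2, n2 / 2, 0.44 * n1 * jit(0.05), 0.40 * n2 * jit(0.05))
    inner = _ellipse(n1, n2, n1 / 2, n2 / 2, 0.38 * n1, 0.34 * n2)
    label[shell] = 1
    mag[shell] = 0.35
    label[inner] = 2
    mag[inner] = 0.85

    vent = _ellipse(
        n1, n2, n1 * 0.55 * jit(0.04), n2 * 0.5, 0.10 * n1, 0.14 * n2, angle_deg=15
    )
    vent &= inner
    label[vent] = 3
    mag[vent] = 0.45

    for i, (dx, dy) in enumerate([(-0.15, -0.12), (0.05, 0.16)]):
        nod = _ellipse(
            n1, n2,
            n1 * (0.5 + dx * jit(0.1)), n2 * (0.5 + dy * jit(0.1)),
            0.06 * n1, 0.05 * n2,
        )
        nod &= inner
        label[nod] = 4 + i
        mag[nod] = 1.0 - 0.25 * i

    support = shell
    mag[~support] = 0.0
    return PhantomImage(magnitude=mag, label_map=label, support_mask=support)


def make_coils(n1: int, n2: int, n_coils: int, seed: int = 0) -> SensitivityMaps:
    """Smooth complex coil maps, Gaussian-lobe model, SoS-normalized.

    Coils sit on a circle around the field of view; each has a broad
    Gaussian magnitude lobe (width ~ half the FOV, so spatial frequencies
    stay well below N/8 cycles per FOV) and a smooth linear phase.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:n1, 0:n2]
    yc, xc = (n1 - 1) / 2, (n2 - 1) / 2
    maps = np.empty((n_coils, n1, n2), dtype=complex)
    for c in range(n_coils):
        th = 2 * np.pi * c / n_coils + 0.1 * rng.standard_normal()
        py = yc + 0.55 * n1 * np.sin(th)
        px = xc + 0.55 * n2 * np.cos(th)
        sig = 0.55 * (n1 + n2) / 2 * (1 + 0.1 * rng.random())
        amp = np.exp(-(((y - py) ** 2 + (x - px) ** 2) / (2 * sig**2)))
        phase = (
            2 * np.pi * (0.2 * rng.standard_normal() * (y - yc) / n1
                         + 0.2 * rng.standard_normal() * (x - xc) / n2)
            + rng.uniform(0, 2 * np.pi)
        )
        maps[c] = amp * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos  # Gaussian lobes are strictly positive, so sos > 0
    return SensitivityMaps(maps=maps)


def make_field(
    n1: int, n2: int, kind: str = "mixed", amplitude_hz: float = 60.0, seed: int = 0
) -> GroundTruthField:
    """Ground-truth dB0 field: smooth polynomial background and/or blobs.

    ``kind``:
      * ``"polynomial"`` -- 2nd-order 2-D polynomial (shim-like residual);
      * ``"blobs"`` -- localized Gaussian off-resonance foci
        (frontal-sinus-like susceptibility);
      * ``"mixed"`` -- both.

    The combined field is scaled so ``max |dB0| = 0.9 * amplitude_hz``.
    """
    if kind not in {"polynomial", "blobs", "mixed"}:
        raise ValueError(f"unknown field kind {kind!r}")
    if amplitude_hz < 0:
        raise ValueError("amplitude_hz must be >= 0")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:n1, 0:n2]
    yn = (y - (n1 - 1) / 2) / (n1 / 2)
    xn = (x - (n2 - 1) / 2) / (n2 / 2)

    poly = np.zeros((n1, n2))
    blobs = np.zeros((n1, n2))
    components: dict = {"kind": kind}

    if kind in ("polynomial", "mixed"):
        coef = rng.standard_normal(6)
        poly = (
            coef[0] + coef[1] * yn + coef[2] * xn
            + coef[3] * yn * xn + coef[4] * yn**2 + coef[5] * xn**2
        )
        if np.max(np.abs(poly)) > 0:
            poly *= 0.6 / np.max(np.abs(poly))
        components["poly_coef"] = coef

    if kind in ("blobs", "mixed"):
        blob_list = []
        for _ in range(rng.integers(1, 4)):
            cy = rng.uniform(-0.6, 0.6)
            cx = rng.uniform(-0.6, 0.6)
            w = rng.uniform(0.1, 0.25)
            a = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
            blobs += a * np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / (2 * w**2))
            blob_list.append({"center": (cy, cx), "width": w, "amplitude": a})
        if np.max(np.abs(blobs)) > 0:
            blobs *= 0.4 / np.max(np.abs(blobs))
        components["blobs"] = blob_list

    total = poly + blobs
    peak = np.max(np.abs(total))
    if peak > 0 and amplitude_hz > 0:
        total = total * (0.9 * amplitude_hz / peak)
    else:
        total = np.zeros_like(total)
    return GroundTruthField(b0_hz=total, components=components)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def acquire(
    phantom: PhantomImage | np.ndarray,
    coils: SensitivityMaps,
    fieldmap: GroundTruthField | np.ndarray | None,
    traj: Trajectory,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> KspaceData:
    """Acquire multi-coil k-space along a trajectory with off-resonance.

    For each trajectory line at physical time t the simulator forms the
    coil images ``S_c(r) m(r) exp(2i pi dB0(r) t)``, Fourier transforms,
    and keeps the acquired ky row; i.i.d. complex Gaussian noise of
    standard deviation ``noise_sigma`` is added per sample.
    """
    m = phantom.magnitude if isinstance(phantom, PhantomImage) else np.asarray(phantom)
    b0 = (
        fieldmap.b0_hz
        if isinstance(fieldmap, GroundTruthField)
        else (np.zeros_like(m, dtype=float) if fieldmap is None else np.asarray(fieldmap))
    )
    if m.shape != b0.shape or coils.maps.shape[1:] != m.shape:
        raise ValueError(
            f"shape mismatch: phantom {m.shape}, field {b0.shape}, "
            f"coils {coils.maps.shape[1:]}"
        )
    if m.shape[1] != traj.n_pe:
        raise ValueError(
            f"phase-encode size {m.shape[1]} != trajectory n_pe {traj.n_pe}"
        )

    coil_imgs = coils.maps * m  # (n_coils, n1, n2)
    times_s = np.asarray(traj.line_times_ms()) / 1000.0
    n_lines = len(traj.lines)
    samples = np.empty((n_lines, coils.n_coils, m.shape[0]), dtype=complex)

    # group lines by acquisition time is pointless (all distinct); FFT per line
    for i, ln in enumerate(traj.lines):
        phase = np.exp(2j * np.pi * b0 * times_s[i])
        ks = fft2c(coil_imgs * phase)
        samples[i] = ks[:, :, ln.ky]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_sigma * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape)
        )
    return KspaceData(samples=samples, traj=traj, noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# rigid-motion time series
# ---------------------------------------------------------------------------


def _rigid_transform(img: np.ndarray, rot_deg: float, s1_px: float, s2_px: float,
                     order: int = 1) -> np.ndarray:
    out = img.astype(float)
    if rot_deg != 0.0:
        out = ndimage.rotate(out, rot_deg, reshape=False, order=order, mode="constant")
    if s1_px != 0.0 or s2_px != 0.0:
        out = ndimage.shift(out, (s1_px, s2_px), order=order, mode="constant")
    return out


def simulate_series(
    phantom: PhantomImage,
    coils: SensitivityMaps,
    base_field: GroundTruthField,
    schedule: MotionSchedule,
    traj: Trajectory,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    pixel_size_mm: float = 1.7,
    max_clip_fraction: float = 0.05,
) -> list[tuple[KspaceData, tuple[float, float, float], GroundTruthField]]:
    """Acquire a rigid-motion time series with pose-dependent field.

    Each volume applies the scheduled rigid pose to the object (bilinear
    resampling), derives the volume's field as the rigidly transported
    base field plus a rotation-scaled linear gradient (see
    :class:`MotionSchedule`), and acquires k-space.  Returns
    ``(kspace, pose, true_field)`` per volume, truth alongside.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = phantom.magnitude.shape
    y, x = np.mgrid[0:n1, 0:n2]
    grad = (y - (n1 - 1) / 2) / (n1 / 2)  # head-foot-like linear gradient

    mass0 = float(phantom.magnitude.sum())
    out = []
    for v, (rot, s1_mm, s2_mm) in enumerate(schedule.poses):
        s1, s2 = s1_mm / pixel_size_mm, s2_mm / pixel_size_mm
        mag_v = _rigid_transform(phantom.magnitude, rot, s1, s2)
        if mass0 > 0 and mag_v.sum() < (1 - max_clip_fraction) * mass0:
            raise ValueError(f"volume {v}: pose moves object out of FOV (> 5% clipped)")
        field_v = _rigid_transform(base_field.b0_hz, rot, s1, s2)
        field_v = field_v + schedule.field_gain_hz_per_deg * rot * grad
        gt = GroundTruthField(b0_hz=field_v, components={"pose": (rot, s1_mm, s2_mm)})
        sub_seed = None if seed is None else int(rng.integers(0, 2**31 - 1))
        ks = acquire(mag_v, coils, gt, traj, noise_sigma=noise_sigma, seed=sub_seed)
        out.append((ks, (rot, s1_mm, s2_mm), gt))
    return out
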