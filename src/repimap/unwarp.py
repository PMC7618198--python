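"""B0-induced geometric distortion along the phase-encode axis.

In EPI the phase-encode bandwidth per pixel is ``1 / (n_pe * esp / R)``;
an off-resonance of dB0 Hz therefore displaces signal by

    shift_vox(r) = dB0(r) * n_pe * esp / R * direction

voxels along the phase-encode axis.  Interleaving echoes in a
blip-rewound readout multiplies both the temporal gap between an echo's
successive lines and its ky stride by the echo count, leaving the
effective dwell per ky line -- and hence the shift -- identical to
conventional single-shot EPI at the same ``R``.

``forward_distort`` applies the warp (a testing reference -- the
synthetic scanner produces distortion physically through per-line phase
evolution) and ``unwarp_image`` inverts it; both use 1-D column-wise
linear interpolation with Jacobian intensity modulation, the standard
pixel-shift model of field-map-based EPI unwarping tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fieldmap import FieldMap
from .trajectory import Trajectory

__all__ = ["ShiftMap", "FoldoverError", "shift_map", "forward_distort", "unwarp_image"]

PE_AXIS = 1  # phase encode along axis 1 throughout the package


class FoldoverError(ValueError):
    """Shift gradient reaches 1 voxel/voxel: columns fold onto themselves."""


@dataclass
class ShiftMap:
    """Signed voxel displacement along the phase-encode axis."""

    shift_vox: np.ndarray
    pe_axis: int = PE_AXIS
    direction: int = 1


def shift_map(field: FieldMap | np.ndarray, traj: Trajectory) -> ShiftMap:
    """Convert a field map in Hz to a voxel-shift map.

    Uses the trajectory's matrix size, echo spacing, parallel-imaging
    factor and blip polarity.  Linear in the field and in ``esp``;
    halving ``R`` doubles the shift.
    """
    b0 = field.b0_hz if isinstance(field, FieldMap) else np.asarray(field)
    if traj.esp_ms <= 0 or traj.n_pe <= 0:
        raise ValueError("trajectory lacks timing information")
    factor = traj.n_pe * (traj.esp_ms * 1e-3) / traj.R * traj.pe_direction
    return ShiftMap(shift_vox=b0 * factor, direction=traj.pe_direction)


def _check_foldover(shift: np.ndarray) -> np.ndarray:
    ds = np.gradient(shift, axis=PE_AXIS)
    if np.any(np.abs(ds) >= 1.0):
        raise FoldoverError(
            f"max |d(shift)/dy| = {np.abs(ds).max():.2f} >= 1: signal fold-over"
        )
    return ds


def forward_distort(image: np.ndarray, shifts: ShiftMap) -> np.ndarray:
    """Warp an image the way a B0 offset warps an EPI acquisition.

    Signal at undistorted position y lands at ``y + shift(y)``; the
    warp conserves 1-D column mass via the Jacobian ``1/(1 + shift')``.
    Solved implicitly by inverting the monotone map y -> y + shift(y)
    per readout column.
    """
    image = np.asarray(image, dtype=float)
    s = shifts.shift_vox
    if image.shape != s.shape:
        raise ValueError("image and shift map shapes differ")
    _check_foldover(s)
    n2 = image.shape[PE_AXIS]
    y = np.arange(n2, dtype=float)
    out = np.empty_like(image)
    for i in range(image.shape[0]):
        yd = y + s[i]  # strictly increasing (no fold-over)
        ysrc = np.interp(y, yd, y)  # y* with y* + s(y*) = y'
        jac = np.gradient(ysrc)  # dy*/dy'
        out[i] = np.interp(ysrc, y, image[i]) * jac
    return out


def unwarp_image(image: np.ndarray, shifts: ShiftMap) -> np.ndarray:
    """Correct a distorted EPI image given its voxel-shift map.

    The shift map is expected in the distorted space (EPI-derived field
    maps live there): the corrected value at y is read from the
    distorted image at ``y + shift(y)``, modulated by ``1 + shift'`` to
    restore column mass.  Round-trips :func:`forward_distort` for
    smooth shift maps.
    """
    image = np.asarray(image, dtype=float)
    s = shifts.shift_vox
    if image.shape != s.shape:
        raise ValueError("image and shift map shapes differ")
    ds = _check_foldover(s)
    n2 = image.shape[PE_AXIS]
    y = np.arange(n2, dtype=float)
    out = np.empty_like(image)
    for i in range(image.shape[0]):
        out[i] = np.interp(y + s[i], y, image[i]) * (1.0 + ds[i])
    return out
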