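"""Shared helpers for the test suite."""

import numpy as np
import pytest

from repimap.fourier import fft2c, ifft2c


def reference_echo_image(phantom, coils, field, traj, echo):
    """Fully sampled reference of one echo image of an rEPI readout.

    Extends the echo's straight ky-t line to every ky row of the grid
    and acquires each row with the corresponding phase evolution: the
    distorted image the echo would show without undersampling.
    """
    n1, n2 = phantom.magnitude.shape
    pts = sorted((ln.ky, ln.t) for ln in traj.lines if ln.echo == echo)
    kys = np.array([p[0] for p in pts], dtype=float)
    ts = np.array([p[1] for p in pts], dtype=float)
    slope, intercept = np.polyfit(kys, ts, 1)
    coil_imgs = coils.maps * phantom.magnitude
    grid = np.zeros((coils.maps.shape[0], n1, n2), dtype=complex)
    for ky in range(n2):
        t_ms = traj.te1_offset_ms + (slope * ky + intercept) * traj.esp_ms
        ksp = fft2c(coil_imgs * np.exp(2j * np.pi * field.b0_hz * t_ms / 1000.0))
        grid[:, :, ky] = ksp[:, :, ky]
    return np.sum(np.conj(coils.maps) * ifft2c(grid), axis=0)
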