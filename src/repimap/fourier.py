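"""Centered orthonormal 2-D Fourier transforms over the last two axes.

k-space index ``floor(N/2)`` is the DC line in both dimensions, matching
the trajectory module's ky indexing.
"""

from __future__ import annotations

import numpy as np

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Image -> centered k-space, unitary normalization."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered k-space -> image, unitary normalization."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
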