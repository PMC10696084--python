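"""Centered, unitary 2-D DFT helpers.

Convention used throughout the package: the DC component sits at the array
center (``fftshift``-ed spectra), transforms are orthonormal (``norm="ortho"``)
so Parseval's identity holds without scale factors, and the frequency-encode
direction runs along rows (last axis).
"""

import numpy as np

__all__ = ["cfft2", "cifft2"]


def cfft2(img: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def cifft2(ksp: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D inverse DFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )
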