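"""Image filter bank producing derived images for feature extraction.

Implements the engine-style filter families used in OCT radiomics:
single-level 2D wavelet subbands, Laplacian-of-Gaussian at physical
sigmas, sign-preserving logarithm, exponential, gradient magnitude,
square root, square, and rotation-invariant uniform LBP. All filters
map an (H, W) float image to one or more derived images of the same
shape; intensity-rescaled point filters preserve the input's dynamic
range so a single bin width remains sensible downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .image import BScanImage, InputError


def wavelet_subbands(pixels: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level separable 2D DWT; four subbands resized to the input shape.

    Subband naming follows the engine convention: LL approximation,
    LH/HL the two detail orientations, HH diagonal detail. Coefficients
    are nearest-neighbour upsampled (2x2 blocks) and cropped.
    """
    h, w = pixels.shape
    ca, (ch, cv, cd) = pywt.dwt2(pixels.astype(float), wavelet, mode="symmetric")
    out = {}
    for name, coeff in (("LL", ca), ("LH", ch), ("HL", cv), ("HH", cd)):
        up = np.kron(coeff, np.ones((2, 2)))[:h, :w]
        out[f"wavelet-{name}"] = up
    return out


def log_filter(pixels: np.ndarray, sigma_mm: float, spacing_mm) -> np.ndarray:
    """Laplacian of Gaussian at a physical scale.

    sigma is given in mm and converted to pixels per axis via the pixel
    spacing; sub-pixel sigmas are clamped to one pixel with a warning.
    """
    sig = [sigma_mm / s for s in spacing_mm]
    if min(sig) < 1.0:
        warnings.warn("LoG sigma below one pixel; clamping", stacklevel=2)
        sig = [max(s, 1.0) for s in sig]
    return ndimage.gaussian_laplace(pixels.astype(float), sigma=sig, mode="nearest", truncate=4.0)


def logarithm_filter(pixels: np.ndarray) -> np.ndarray:
    """Sign-preserving scaled logarithm, rescaled to the input's max magnitude."""
    x = pixels.astype(float)
    y = np.sign(x) * np.log1p(np.abs(x))
    m_in, m_out = np.abs(x).max(), np.abs(y).max()
    if m_out > 0:
        y = y * (m_in / m_out)
    return y


def exponential_filter(pixels: np.ndarray) -> np.ndarray:
    """exp(c*x) with c chosen so the maximum magnitude maps to itself."""
    x = pixels.astype(float)
    m = np.abs(x).max()
    if m == 0:
        return np.ones_like(x)
    c = np.log(m) / m if m > 1 else 1.0
    return np.exp(c * x)


def square_filter(pixels: np.ndarray) -> np.ndarray:
    """Squared intensities rescaled back to the input's max magnitude."""
    x = pixels.astype(float)
    m = np.abs(x).max()
    if m == 0:
        return np.zeros_like(x)
    return x**2 / m


def squareroot_filter(pixels: np.ndarray) -> np.ndarray:
    """Sign-preserving square root rescaled to the input's max magnitude."""
    x = pixels.astype(float)
    m = np.abs(x).max()
    return np.sign(x) * np.sqrt(np.abs(x) * m)


def gradient_filter(pixels: np.ndarray, spacing_mm=(1.0, 1.0)) -> np.ndarray:
    """Gradient magnitude of first differences, spacing-aware."""
    gr, gc = np.gradient(pixels.astype(float), spacing_mm[0], spacing_mm[1])
    return np.hypot(gr, gc)


def lbp2d_filter(pixels: np.ndarray, radius: int = 1, n_points: int = 8) -> np.ndarray:
    """Rotation-invariant uniform local-binary-pattern code image (codes 0..P+1)."""
    x = np.asarray(pixels)
    if np.allclose(x, np.rint(x)):
        x = np.rint(x).astype(np.int64)  # integer input avoids float-plateau ambiguity
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return local_binary_pattern(x, P=n_points, R=radius, method="uniform")


def apply_filter(image: BScanImage, spec: str, *, sigmas_mm=(3.0, 5.0),
                 wavelet: str = "coif1", lbp_radius: int = 1,
                 lbp_points: int = 8) -> dict[str, np.ndarray]:
    """Apply one named filter family; returns {derived-image-name: pixels}.

    ``spec`` is one of: original, wavelet, log_sigma, logarithm,
    exponential, gradient, squareroot, square, lbp-2D.
    """
    px = np.asarray(image.pixels, dtype=float)
    if spec == "original":
        return {"original": px}
    if spec == "wavelet":
        return wavelet_subbands(px, wavelet)
    if spec == "log_sigma":
        out = {}
        for s in sigmas_mm:
            name = f"log-sigma-{str(float(s)).replace('.', '-')}-mm-3D"
            out[name] = log_filter(px, s, image.spacing_mm)
        return out
    if spec == "logarithm":
        return {"logarithm": logarithm_filter(px)}
    if spec == "exponential":
        return {"exponential": exponential_filter(px)}
    if spec == "gradient":
        return {"gradient": gradient_filter(px, image.spacing_mm)}
    if spec == "squareroot":
        return {"squareroot": squareroot_filter(px)}
    if spec == "square":
        return {"square": square_filter(px)}
    if spec == "lbp-2D":
        return {"lbp-2D": lbp2d_filter(px, lbp_radius, lbp_points)}
    raise InputError(f"unknown filter spec: {spec!r}")
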