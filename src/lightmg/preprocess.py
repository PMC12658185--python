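"""Image-level handcrafted preprocessing for retinal-detachment fundus photographs.

The chain enhances detachment-related structure before classification:
grayscale conversion, heavy Gaussian smoothing, intensity amplification, a
negative transform of the smoothed image, a linear blend with a fixed offset,
and a circular crop that removes the dark camera background around the fundus
disc.  Every stage operates on real-valued images in the nominal 0-255 range;
rounding to 8-bit happens only on file write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

# ITU-R BT.601 luma weights: Y = 0.299 R + 0.587 G + 0.114 B
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_KERNEL_SIZE = 99
DEFAULT_SIGMA = 10.0
DEFAULT_SCALE = 5.0
DEFAULT_OFFSET = 130.0


@dataclass(frozen=True)
class GaussianKernel:
    """Discrete, normalized isotropic Gaussian convolution kernel.

    Weights are proportional to exp(-(x^2+y^2)/(2 sigma^2)) on the centred
    integer lattice and renormalized to sum to one, so constant images are
    fixed points of the blur.
    """

    weights: np.ndarray
    size: int
    sigma: float


@dataclass(frozen=True)
class ROIImage:
    """Grayscale image restricted to a circular region of interest.

    Pixels outside the disc mask are exactly zero.
    """

    pixels: np.ndarray
    mask: np.ndarray
    center: tuple[float, float]
    radius: float


def _as_float(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image (channel order red, green, blue) to
    grayscale via Y = 0.299 R + 0.587 G + 0.114 B.

    Values stay real-valued; no rounding is applied.
    """
    arr = _as_float(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {arr.shape}")
    return arr @ GRAY_WEIGHTS


def gaussian_kernel(size: int = DEFAULT_KERNEL_SIZE, sigma: float = DEFAULT_SIGMA) -> GaussianKernel:
    """Build the normalized discrete 2-D Gaussian kernel used by the blur stage."""
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    # exponent split keeps the 2-D kernel exactly rank-1 (separable)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    weights = np.outer(g1, g1)
    weights /= weights.sum()
    return GaussianKernel(weights=weights, size=size, sigma=sigma)


def gaussian_blur(img: np.ndarray, kernel: GaussianKernel | None = None) -> np.ndarray:
    """Convolve a grayscale image with a normalized Gaussian kernel.

    Borders are handled by reflection so the fundus rim is not darkened.
    The separable structure of the Gaussian is exploited: two 1-D passes
    instead of one K x K convolution.
    """
    if kernel is None:
        kernel = gaussian_kernel()
    arr = _as_float(img)
    half = kernel.size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * kernel.sigma**2))
    g1 /= g1.sum()
    out = ndimage.correlate1d(arr, g1, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, g1, axis=1, mode="reflect")
    return out


def brighten(img: np.ndarray, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Multiply each pixel by ``scale``, capping the result at 255."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return np.minimum(_as_float(img) * scale, 255.0)


def negative_transform(blurred: np.ndarray, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Amplify the (blurred) image by ``scale``, cap at 255, then invert:
    out = 255 - min(scale * p, 255)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 255.0 - np.minimum(_as_float(blurred) * scale, 255.0)


def linear_blend(a: np.ndarray, b: np.ndarray, offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Pixel-wise sum of two images plus a brightness offset, clipped to [0, 255]."""
    a = _as_float(a)
    b = _as_float(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.clip(a + b + offset, 0.0, 255.0)


def circular_crop(
    img: np.ndarray,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> ROIImage:
    """Zero out everything outside a circular disc (the fundus field of view).

    Defaults: disc centred on the image, radius min(H, W) / 2.
    """
    arr = _as_float(img)
    h, w = arr.shape[:2]
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 2.0
    if radius <= 0:
        raise ValueError("radius must be positive")
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("center must lie inside the image")
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
    return ROIImage(pixels=np.where(mask, arr, 0.0), mask=mask, center=center, radius=radius)


@dataclass(frozen=True)
class PreprocessParams:
    kernel_size: int = DEFAULT_KERNEL_SIZE
    sigma: float = DEFAULT_SIGMA
    scale: float = DEFAULT_SCALE
    offset: float = DEFAULT_OFFSET
    center: tuple[float, float] | None = None
    radius: float | None = None


def preprocess_image(img: np.ndarray, params: PreprocessParams | None = None) -> ROIImage:
    """Full image-level chain on one RGB fundus photograph.

    gray -> Gaussian blur(gray) -> brighten(gray) and negative(blur) ->
    linear blend with offset -> circular crop.  Deterministic; output shape
    equals input spatial shape.
    """
    p = params or PreprocessParams()
    gray = to_grayscale(img)
    blur = gaussian_blur(gray, gaussian_kernel(p.kernel_size, p.sigma))
    bright = brighten(gray, p.scale)
    neg = negative_transform(blur, p.scale)
    blend = linear_blend(bright, neg, p.offset)
    return circular_crop(blend, center=p.center, radius=p.radius)


class FundusPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer wrapping :func:`preprocess_image`.

    ``transform`` maps an iterable of H x W x 3 RGB arrays to an array of
    H x W ROI grayscale images (outside-disc pixels zero).
    """

    def __init__(
        self,
        kernel_size: int = DEFAULT_KERNEL_SIZE,
        sigma: float = DEFAULT_SIGMA,
        scale: float = DEFAULT_SCALE,
        offset: float = DEFAULT_OFFSET,
    ):
        self.kernel_size = kernel_size
        self.sigma = sigma
        self.scale = scale
        self.offset = offset

    def fit(self, X, y=None):
        # nothing to learn; validate parameters eagerly
        gaussian_kernel(self.kernel_size, self.sigma)
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        params = PreprocessParams(
            kernel_size=self.kernel_size, sigma=self.sigma, scale=self.scale, offset=self.offset
        )
        return np.stack([preprocess_image(img, params).pixels for img in X])
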