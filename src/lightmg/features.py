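"""Feature-level handcrafted descriptors for fundus texture analysis.

Three operator families:

* **AM-FM decomposition** of the green channel: the image is smoothed by a
  Gaussian at each scale sigma_s; the amplitude map A_s is the absolute value
  of the smoothed image (local intensity) and the frequency map F_s is the
  gradient magnitude of the smoothed image (local spatial variation).
* **Gabor filter bank**: Gaussian-windowed complex sinusoids over a grid of
  4 frequencies x 6 orientations x 2 dyadic scales = 48 filters; each response
  map is aggregated to its mean magnitude, yielding a 48-vector per image.
* **RGB -> HSV** colour-space conversion (hue in degrees, saturation and
  value in [0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage import color
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import gaussian_blur, gaussian_kernel, to_grayscale

DEFAULT_AMFM_SIGMAS = (1.0, 2.0, 4.0)
DEFAULT_GABOR_FREQS = (0.05, 0.1, 0.2, 0.4)


@dataclass(frozen=True)
class AMFMStack:
    """Per-scale amplitude and frequency-magnitude maps of one image."""

    scales: tuple[float, ...]
    amplitude_maps: list[np.ndarray]
    frequency_maps: list[np.ndarray]


def _sigma_to_kernel_size(sigma: float) -> int:
    size = 2 * int(math.ceil(3.0 * sigma)) + 1
    return max(size, 3)


def amfm_decompose(green: np.ndarray, sigmas=DEFAULT_AMFM_SIGMAS) -> AMFMStack:
    """Decompose one channel into amplitude/frequency maps at several scales.

    For each sigma_s: I_s = I * G_s (normalized Gaussian, reflected borders),
    A_s = |I_s|, F_s = ||grad I_s|| via central differences (one-sided at the
    borders).  Sigmas must be strictly increasing.
    """
    sigmas = tuple(float(s) for s in sigmas)
    if len(sigmas) == 0:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in sigmas) or any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigmas must be positive and strictly increasing")
    arr = np.asarray(green, dtype=np.float64)
    amps, freqs = [], []
    for s in sigmas:
        smoothed = gaussian_blur(arr, gaussian_kernel(_sigma_to_kernel_size(s), s))
        amps.append(np.abs(smoothed))
        gr, gc = np.gradient(smoothed)
        freqs.append(np.hypot(gr, gc))
    return AMFMStack(scales=sigmas, amplitude_maps=amps, frequency_maps=freqs)


def amfm_feature_vector(stack: AMFMStack) -> list[np.ndarray]:
    """Interleave the per-scale maps as [A_1, F_1, A_2, F_2, ..., A_S, F_S]."""
    out: list[np.ndarray] = []
    for a, f in zip(stack.amplitude_maps, stack.frequency_maps):
        out.extend([a, f])
    return out


def gabor_kernel(
    frequency: float,
    theta: float,
    m: int = 0,
    a: float = 2.0,
    sigma_i: float | None = None,
    sigma_j: float | None = None,
    zero_mean: bool = True,
) -> np.ndarray:
    """Complex Gabor filter at one (frequency, orientation, scale) point.

    Coordinates are rotated by theta and shrunk by a**(-m); the Gaussian
    envelope (widths sigma_i along the modulated axis, sigma_j across it)
    is modulated by a complex sinusoid of frequency ``frequency`` along the
    rotated i' axis.  With ``zero_mean`` the kernel mean is subtracted so a
    constant image yields a zero response.

    Default window widths follow the one-octave-bandwidth rule
    sigma = 0.56 / frequency.
    """
    if a <= 1:
        raise ValueError("scaling factor a must exceed 1")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if sigma_i is None:
        sigma_i = 0.56 / frequency
    if sigma_j is None:
        sigma_j = 0.56 / frequency
    # coordinate shrink a^-m widens the effective support by a^m
    half = int(math.ceil(3.5 * max(sigma_i, sigma_j) * a**m))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    jj, ii = np.meshgrid(ax, ax)  # ii: row offset, jj: column offset
    scale = a ** (-float(m))
    i_p = scale * (ii * np.cos(theta) + jj * np.sin(theta))
    j_p = scale * (-ii * np.sin(theta) + jj * np.cos(theta))
    envelope = (1.0 / (2.0 * np.pi * sigma_i * sigma_j)) * np.exp(
        -(i_p**2 / (2.0 * sigma_i**2) + j_p**2 / (2.0 * sigma_j**2))
    )
    kern = envelope * np.exp(2j * np.pi * frequency * i_p)
    if zero_mean:
        kern = kern - kern.mean()
    return kern


def gabor_bank(
    gray: np.ndarray,
    frequencies=DEFAULT_GABOR_FREQS,
    M: int = 6,
    S: int = 2,
    a: float = 2.0,
    sigma_i: float | None = None,
    sigma_j: float | None = None,
) -> np.ndarray:
    """Apply the full Gabor bank and aggregate each response to one scalar.

    Orientations are theta_n = n pi / M for n = 0..M-1 and scales m = 0..S-1.
    Each of the len(frequencies) * M * S response maps is summarized by the
    mean magnitude of the complex filter response, giving 48 features with
    the default 4 x 6 x 2 grid.  Output is ordered frequency-major, then
    orientation, then scale.
    """
    if M < 1 or S < 1:
        raise ValueError("M and S must be >= 1")
    if a <= 1:
        raise ValueError("scaling factor a must exceed 1")
    arr = np.asarray(gray, dtype=np.float64)
    feats = []
    for w in frequencies:
        for n in range(M):
            theta = n * np.pi / M
            for m in range(S):
                kern = gabor_kernel(w, theta, m=m, a=a, sigma_i=sigma_i, sigma_j=sigma_j)
                # reflect-pad so constant images give exactly zero response
                half = kern.shape[0] // 2
                padded = _pad_reflect(arr, half)
                resp = fftconvolve(padded, kern, mode="valid")
                feats.append(np.abs(resp).mean())
    return np.asarray(feats)


def _pad_reflect(arr: np.ndarray, width: int) -> np.ndarray:
    """Reflect-pad by any width (numpy's reflect caps at the axis length,
    so wide kernels need repeated passes)."""
    while width > 0:
        step = min(width, min(arr.shape) - 1)
        arr = np.pad(arr, step, mode="reflect")
        width -= step
    return arr


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image (0-255) to HSV with hue in degrees [0, 360).

    Returns an H x W x 3 float array: hue, saturation in [0,1], value in [0,1].
    Hue of achromatic pixels is 0.
    """
    arr = np.asarray(img, dtype=np.float64) / 255.0
    hsv = color.rgb2hsv(arr)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; returns float RGB on the 0-255 scale."""
    h = np.asarray(hsv, dtype=np.float64).copy()
    h[..., 0] = (h[..., 0] % 360.0) / 360.0
    return color.hsv2rgb(h) * 255.0


class HandcraftedFeatures(BaseEstimator, TransformerMixin):
    """Per-image scalar descriptor table: 48 Gabor features on the grayscale
    image, mean A_s / mean F_s per AM-FM scale of the green channel, and the
    three HSV channel means.

    ``transform`` maps an iterable of RGB images to an (n, 48 + 2S + 3) array.
    """

    def __init__(self, amfm_sigmas=DEFAULT_AMFM_SIGMAS, gabor_freqs=DEFAULT_GABOR_FREQS,
                 M: int = 6, S: int = 2, a: float = 2.0):
        self.amfm_sigmas = amfm_sigmas
        self.gabor_freqs = gabor_freqs
        self.M = M
        self.S = S
        self.a = a

    def fit(self, X, y=None):
        self.feature_names_ = self._feature_names()
        return self

    def _feature_names(self) -> list[str]:
        names = [
            f"gabor_f{w:g}_o{n}_s{m}"
            for w in self.gabor_freqs
            for n in range(self.M)
            for m in range(self.S)
        ]
        for s in self.amfm_sigmas:
            names += [f"amfm_meanA_s{s:g}", f"amfm_meanF_s{s:g}"]
        names += ["hsv_mean_h", "hsv_mean_s", "hsv_mean_v"]
        return names

    def transform(self, X):
        rows = []
        for img in X:
            gray = to_grayscale(img)
            gvec = gabor_bank(gray, self.gabor_freqs, M=self.M, S=self.S, a=self.a)
            stack = amfm_decompose(np.asarray(img, dtype=np.float64)[..., 1], self.amfm_sigmas)
            amfm = [v for a_map, f_map in zip(stack.amplitude_maps, stack.frequency_maps)
                    for v in (a_map.mean(), f_map.mean())]
            hsv = rgb_to_hsv(img)
            rows.append(np.concatenate([gvec, amfm, hsv.reshape(-1, 3).mean(axis=0)]))
        return np.stack(rows)
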