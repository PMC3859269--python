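"""Image-quality metrics: RMSE, CNR, SSIM and MSSIM.

The structural similarity index compares local luminance, contrast and
structure between a reference and a test image inside a sliding window:

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + ... )  -- specifically
    SSIM(x, y) = ((2 mu_x mu_y + C1)(sigma_xy + C2))
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

with stabilizers C_m = (K_m L)^2 where L is the dynamic range of the
reference and K_m << 1.  MSSIM is the plain mean of the local SSIM values
over all fully contained windows and serves as the scalar quality score of
a reconstructed slice.

Conventions: windows slide with stride 1 and must fit entirely inside the
image; window statistics use population (1/n) variance; the default window
is an 8x8 uniform box, with an odd-sized Gaussian window available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WindowKind",
    "SsimParams",
    "RoiSpec",
    "rmse",
    "cnr",
    "ssim_map",
    "mssim",
]


class WindowKind(str, Enum):
    UNIFORM = "uniform"
    GAUSSIAN = "gaussian"


@dataclass
class SsimParams:
    """Parameters of the SSIM computation.

    ``L`` of ``None`` means "use the joint dynamic range (max - min) of
    the two images being compared", falling back to 1 when both are
    constant.
    """

    K1: float = 0.01
    K2: float = 0.03
    L: float | None = None
    window_size: int = 8
    window_kind: WindowKind = WindowKind.UNIFORM
    gaussian_sigma: float = 1.5

    def validate(self) -> None:
        if not 0 < self.K1 < 1 or not 0 < self.K2 < 1:
            raise ValueError("K1 and K2 must be small constants in (0, 1)")
        if self.L is not None and not self.L > 0:
            raise ValueError("L must be > 0 when given")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.window_kind is WindowKind.GAUSSIAN and self.window_size % 2 == 0:
            raise ValueError("gaussian windows must have odd size")
        if not self.gaussian_sigma > 0:
            raise ValueError("gaussian_sigma must be > 0")


@dataclass
class RoiSpec:
    """Signal and background regions for CNR, as boolean masks over the
    image; the regions must be disjoint and nonempty."""

    signal_region: np.ndarray
    background_region: np.ndarray

    def validate(self, shape) -> None:
        s = np.asarray(self.signal_region, dtype=bool)
        b = np.asarray(self.background_region, dtype=bool)
        if s.shape != shape or b.shape != shape:
            raise ValueError("ROI masks must match the image shape")
        if not s.any() or not b.any():
            raise ValueError("ROI regions must be nonempty")
        if (s & b).any():
            raise ValueError("signal and background regions must be disjoint")
        if b.sum() < 2:
            raise ValueError("background region needs at least 2 pixels")


def rmse(X: np.ndarray, Y: np.ndarray) -> float:
    """Root mean square error sqrt(mean((X - Y)^2)); symmetric, 0 iff
    the arrays are equal."""
    a = np.asarray(X, dtype=np.float64)
    b = np.asarray(Y, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cnr(image: np.ndarray, roi: RoiSpec) -> float:
    """Contrast-to-noise ratio |mu_signal - mu_background| / sigma_background
    (population standard deviation).  Invariant to adding a constant to the
    whole image; infinity (with a warning) for a perfectly flat background."""
    img = np.asarray(image, dtype=np.float64)
    roi.validate(img.shape)
    s = img[np.asarray(roi.signal_region, dtype=bool)]
    b = img[np.asarray(roi.background_region, dtype=bool)]
    sigma = float(b.std())
    contrast = abs(float(s.mean()) - float(b.mean()))
    if sigma == 0.0:
        warnings.warn("background region has zero standard deviation; CNR is infinite")
        return float("inf")
    return contrast / sigma


def _window_moments(a: np.ndarray, p: SsimParams):
    """Per-window mean of ``a`` and of elementwise products, stride 1,
    windows fully inside the image."""
    w = p.window_size
    win = sliding_window_view(a, (w, w))
    if p.window_kind is WindowKind.UNIFORM:
        return win.mean(axis=(-2, -1))
    half = (w - 1) / 2
    g1 = np.exp(-0.5 * ((np.arange(w) - half) / p.gaussian_sigma) ** 2)
    g = np.outer(g1, g1)
    g /= g.sum()
    return np.einsum("ijkl,kl->ij", win, g)


def ssim_map(x: np.ndarray, y: np.ndarray, p: SsimParams | None = None) -> np.ndarray:
    """Local SSIM over all sliding windows.

    Returns an array of shape (H - w + 1, W - w + 1); each entry is at most
    1 and equals 1 exactly where the two windows coincide.  Symmetric in
    its arguments (the default derives L from the joint dynamic range of
    both images)."""
    if p is None:
        p = SsimParams()
    p.validate()
    a = np.asarray(x, dtype=np.float64)
    b = np.asarray(y, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("ssim_map expects 2D images")
    w = p.window_size
    if a.shape[0] < w or a.shape[1] < w:
        raise ValueError(f"image {a.shape} is smaller than the {w}x{w} window")

    L = p.L
    if L is None:
        ptp = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        L = ptp if ptp > 0 else 1.0
    c1 = (p.K1 * L) ** 2
    c2 = (p.K2 * L) ** 2

    mu_x = _window_moments(a, p)
    mu_y = _window_moments(b, p)
    # population second moments
    m_xx = _window_moments(a * a, p)
    m_yy = _window_moments(b * b, p)
    m_xy = _window_moments(a * b, p)
    var_x = m_xx - mu_x ** 2
    var_y = m_yy - mu_y ** 2
    cov = m_xy - mu_x * mu_y

    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return num / den


def mssim(X: np.ndarray, Y: np.ndarray, p: SsimParams | None = None) -> float:
    """Mean SSIM: the average of :func:`ssim_map` over all local windows.
    At most 1; exactly 1 iff the images are identical."""
    return float(ssim_map(X, Y, p).mean())
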