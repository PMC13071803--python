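"""Resolution treatments, edge operators and image similarity.

Downsampling follows the cubic-convolution convention of the common
reference resize routines: the Keys kernel with a = -0.5, pixel-centre
coordinate mapping ``x_in = (i_out + 0.5) * scale - 0.5``, replicate (clamp)
edge handling, and — when shrinking with antialiasing on — kernel support
widened by the scale factor so the weighted neighbourhood covers the
footprint of the output pixel.  Nearest-neighbour uses the same centre
mapping rounded to the closest input pixel and never introduces new values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def keys_cubic(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic convolution kernel of Keys (support 2, partition of unity)."""
    x = np.abs(np.asarray(x, float))
    out = np.zeros_like(x)
    m1 = x <= 1
    m2 = (x > 1) & (x < 2)
    out[m1] = (a + 2) * x[m1] ** 3 - (a + 3) * x[m1] ** 2 + 1
    out[m2] = a * (x[m2] ** 3 - 5 * x[m2] ** 2 + 8 * x[m2] - 4)
    return out


from functools import lru_cache


@lru_cache(maxsize=64)
def _resample_weights_cached(n_in: int, n_out: int, antialias: bool):
    w = _resample_weights(n_in, n_out, antialias)
    w.setflags(write=False)
    return w


def _resample_weights(n_in: int, n_out: int, antialias: bool) -> np.ndarray:
    """Dense (n_out, n_in) row-stochastic weight matrix for one axis."""
    scale = n_in / n_out
    if scale < 1:
        raise ValueError("upsampling is out of scope")
    width = scale if (antialias and scale > 1) else 1.0
    support = 2.0 * width
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        centre = (i + 0.5) * scale - 0.5
        lo = int(np.floor(centre - support)) + 1
        hi = int(np.floor(centre + support))
        taps = np.arange(lo, hi + 1)
        weights = keys_cubic((taps - centre) / width) / width
        taps = np.clip(taps, 0, n_in - 1)  # replicate boundary
        np.add.at(w[i], taps, weights)
        w[i] /= w[i].sum()
    return w


def downsample_bicubic(
    image: np.ndarray, out_size: tuple, antialias: bool = True
) -> np.ndarray:
    """Separable cubic-convolution shrink.  Values may overshoot the input
    range (no clipping); constant images are reproduced exactly."""
    image = np.asarray(image, float)
    rows, cols = image.shape
    nr, nc = int(out_size[0]), int(out_size[1])
    if nr > rows or nc > cols:
        raise ValueError("upsampling is out of scope")
    wr = _resample_weights_cached(rows, nr, antialias)
    wc = _resample_weights_cached(cols, nc, antialias)
    return wr @ image @ wc.T


def downsample_nearest(image: np.ndarray, out_size: tuple) -> np.ndarray:
    """Nearest-neighbour shrink with the same centre mapping, no
    antialiasing: each output value is copied from one input pixel."""
    image = np.asarray(image)
    rows, cols = image.shape
    nr, nc = int(out_size[0]), int(out_size[1])
    if nr > rows or nc > cols:
        raise ValueError("upsampling is out of scope")
    sr, sc = rows / nr, cols / nc
    ri = np.clip(np.floor((np.arange(nr) + 0.5) * sr - 0.5 + 0.5).astype(int), 0, rows - 1)
    ci = np.clip(np.floor((np.arange(nc) + 0.5) * sc - 0.5 + 0.5).astype(int), 0, cols - 1)
    return image[np.ix_(ri, ci)]


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude with the standard 3x3 Sobel kernels, reflect
    boundary handling."""
    image = np.asarray(image, float)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    value, _ = ncc_flagged(a, b, mask)
    return value


def ncc_flagged(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, bool]:
    """Pearson correlation of two equal-shape images, optionally restricted
    to ``mask``.  A zero-variance (flat) input yields (0.0, True)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is not None:
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0, True
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0)), False


# ---------------------------------------------------------------------------
# Preprocessing chains
# ---------------------------------------------------------------------------
# A chain is a sequence of named steps applied in order to a float image.
# The same chain (modulo the polarity inversion) is applied to target
# radiographs and DRRs so that their edge maps are comparable.

def _stretch(image: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    # affine percentile normalisation, no clipping: values may leave [0, 1].
    # NCC is affine-invariant, so clipping would only inject a nonlinearity
    # that depends on which region the percentiles were computed over
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return (image - lo) / (hi - lo)


def _neglog(im: np.ndarray) -> np.ndarray:
    # Beer-Lambert linearisation: -log(counts) equals the attenuation line
    # integral up to an affine offset; clamp relative to the brightest pixel
    # so noise-floor pixels cannot produce unbounded spikes
    floor = 1e-4 * max(float(im.max()), 1e-300)
    return -np.log(np.maximum(im, floor))


_CHAIN_STEPS = {
    "invert": lambda im: im.max() - im,
    "neglog": _neglog,
    "stretch": _stretch,
    "sobel": sobel_edges,
}

DEFAULT_TARGET_CHAIN = ("neglog", "stretch", "sobel")
#: per-evaluation DRR chain: the percentile stretch is affine, and NCC is
#: affine-invariant, so it is omitted from the hot path
DEFAULT_DRR_CHAIN = ("sobel",)


def preprocess(image: np.ndarray, chain=DEFAULT_TARGET_CHAIN) -> np.ndarray:
    """Apply a named filter chain; the empty chain is the identity."""
    out = np.asarray(image, float)
    for step in chain:
        try:
            fn = _CHAIN_STEPS[step]
        except KeyError:
            raise ValueError(f"unknown preprocessing step {step!r}") from None
        out = fn(out)
    return out
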