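"""Per-pixel gray-level co-occurrence (GLCM) statistics.

For every pixel, a symmetric normalized GLCM is formed from all distance-1
neighbor pairs whose *both* endpoints lie within the (2k+1)x(2k+1) window
centred on the pixel.  The four offset directions (0 deg, 45 deg, 90 deg,
135 deg) are each normalized and then averaged, and 13 classic co-occurrence
metrics are evaluated on the averaged matrix.

Conventions (fixed and relied on by the tests):

* quantization: uniform bins over ``[lo, hi]``; the top edge maps into the
  last bin; a constant image quantizes to level 0;
* entropies use log base 2, with ``0 * log 0 = 0``;
* correlation is defined as 0 when either marginal SD is 0 (single-level
  window); the information measure of correlation 1 is 0 when ``HX = 0``;
* slices are reflection-padded so every window is complete.
"""

from __future__ import annotations

import numpy as np

METRIC_NAMES = (
    "contrast",
    "correlation",
    "energy",
    "entropy",
    "homogeneity",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "imc1",
)

# Symmetric distance-1 offsets: 0, 45, 90, 135 degrees (row, col).
_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def quantize(img: np.ndarray, n_levels: int, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Quantize intensities into ``n_levels`` uniform bins over [lo, hi]."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    img = np.asarray(img, dtype=float)
    lo = float(img.min() if lo is None else lo)
    hi = float(img.max() if hi is None else hi)
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.int64)
    codes = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(codes, 0, n_levels - 1)


def _integral(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    return s


def _box_sum(sat: np.ndarray, r0: int, r1: int, c0: int, c1: int, out_shape) -> np.ndarray:
    """Windowed sums of the underlying array over rectangles
    ``[y+r0, y+r1] x [x+c0, x+c1]`` for every output pixel ``(y, x)``, where
    the underlying array was padded by ``pad`` on each side and the output is
    the unpadded grid.  Coordinates are relative to the padded array origin.
    """
    h, w = out_shape
    return (
        sat[r1 + 1 : r1 + 1 + h, c1 + 1 : c1 + 1 + w]
        - sat[r0 : r0 + h, c1 + 1 : c1 + 1 + w]
        - sat[r1 + 1 : r1 + 1 + h, c0 : c0 + w]
        + sat[r0 : r0 + h, c0 : c0 + w]
    )


def glcm_probability_stack(codes: np.ndarray, n_levels: int, window: int, pixel_mask=None):
    """Per-pixel direction-averaged symmetric GLCM.

    Returns ``(pair_codes, P)`` where ``pair_codes`` is an int array of the
    occurring pair codes ``i * n_levels + j`` and ``P`` has shape
    ``(len(pair_codes), H, W)``, each pixel's matrix summing to 1.  With a
    boolean ``pixel_mask``, matrices are evaluated only at the masked pixels
    and ``P`` has shape ``(len(pair_codes), mask.sum())``.
    """
    if window < 2 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    codes = np.asarray(codes)
    h, w = codes.shape
    if window > min(h, w):
        raise ValueError(f"window {window} larger than slice {codes.shape}")
    k = window // 2
    pad = k + 1  # room for the +1 offsets at the window edge
    cp = np.pad(codes, pad, mode="reflect")

    # ordered pair-code maps per direction, anchored at the first pixel
    per_dir = []
    for dy, dx in _OFFSETS:
        a = cp
        b = np.roll(np.roll(cp, -dy, axis=0), -dx, axis=1)
        fwd = a * n_levels + b  # ordered (a, b)
        bwd = b * n_levels + a  # ordered (b, a)
        per_dir.append((dy, dx, fwd, bwd))

    # restrict to codes that can occur in some window
    lo, hi_r, hi_c = pad - k, pad + h + k, pad + w + k
    all_codes = np.unique(
        np.concatenate(
            [d[m][lo:hi_r, lo:hi_c].ravel() for d in per_dir for m in (2, 3)]
        )
    )
    lut = np.full(n_levels * n_levels, -1, dtype=np.int64)
    lut[all_codes] = np.arange(len(all_codes))

    if pixel_mask is not None:
        sel = np.flatnonzero(np.asarray(pixel_mask, dtype=bool).ravel())
    else:
        sel = None
    npix = h * w if sel is None else len(sel)
    pix_idx = np.arange(npix, dtype=np.int64)
    P = np.zeros((len(all_codes), npix), dtype=np.float64)
    for dy, dx, fwd, bwd in per_dir:
        # anchors p with both p and p+d inside the window around (y, x):
        # rows [y-k, y+k-dy], cols [x-k+max(-dx,0), x+k-max(dx,0)]
        r0, r1 = -k, k - dy
        c0, c1 = -k + max(-dx, 0), k - max(dx, 0)
        n_pairs = (r1 - r0 + 1) * (c1 - c0 + 1)
        weight = 1.0 / (4.0 * 2.0 * n_pairs)  # symmetric pairs, 4 directions
        for ordered in (fwd, bwd):
            mapped = lut[ordered]
            chunks = []
            for oy in range(r0, r1 + 1):
                for ox in range(c0, c1 + 1):
                    sh = mapped[pad + oy : pad + oy + h, pad + ox : pad + ox + w].reshape(-1)
                    if sel is not None:
                        sh = sh[sel]
                    chunks.append(sh * npix + pix_idx)
            counts = np.bincount(
                np.concatenate(chunks), minlength=len(all_codes) * npix
            ).reshape(len(all_codes), npix)
            P += weight * counts
    if sel is None:
        return all_codes, P.reshape(len(all_codes), h, w)
    return all_codes, P


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_metrics_from_stack(pair_codes: np.ndarray, P: np.ndarray, n_levels: int) -> dict:
    """Evaluate the 13 co-occurrence metrics on a per-pixel GLCM stack."""
    i = (pair_codes // n_levels).astype(np.float64)
    j = (pair_codes % n_levels).astype(np.float64)
    npairs = P.shape[0]
    out_shape = P.shape[1:]
    flat = P.reshape(npairs, -1)

    # marginals (symmetric GLCM: px == py), via one-hot matmuls
    ii = (pair_codes // n_levels).astype(np.int64)
    jj = (pair_codes % n_levels).astype(np.int64)
    m_px = (np.arange(n_levels)[:, None] == ii[None, :]).astype(np.float64)
    px = m_px @ flat
    levels = np.arange(n_levels, dtype=np.float64)[:, None]
    mu = (levels * px).sum(axis=0)
    var_x = ((levels - mu) ** 2 * px).sum(axis=0)
    sd_x = np.sqrt(var_x)

    iw = i[:, None]
    jw = j[:, None]
    contrast = ((iw - jw) ** 2 * flat).sum(axis=0)
    eij = (iw * jw * flat).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(sd_x > 0, (eij - mu * mu) / np.where(sd_x > 0, var_x, 1.0), 0.0)
    energy = (flat**2).sum(axis=0)
    entropy = -_xlog2x(flat).sum(axis=0)
    homogeneity = (flat / (1.0 + (iw - jw) ** 2)).sum(axis=0)
    variance = ((iw - mu) ** 2 * flat).sum(axis=0)

    # sum (i + j) and difference |i - j| marginals
    m_sum = (np.arange(2 * n_levels - 1)[:, None] == (ii + jj)[None, :]).astype(np.float64)
    psum = m_sum @ flat
    ks = np.arange(2 * n_levels - 1, dtype=np.float64)[:, None]
    sum_average = (ks * psum).sum(axis=0)
    sum_variance = ((ks - sum_average) ** 2 * psum).sum(axis=0)
    sum_entropy = -_xlog2x(psum).sum(axis=0)

    m_diff = (np.arange(n_levels)[:, None] == np.abs(ii - jj)[None, :]).astype(np.float64)
    pdiff = m_diff @ flat
    kd = levels
    difference_average = (kd * pdiff).sum(axis=0)
    difference_variance = ((kd - difference_average) ** 2 * pdiff).sum(axis=0)
    difference_entropy = -_xlog2x(pdiff).sum(axis=0)

    # information measure of correlation 1
    hx = -_xlog2x(px).sum(axis=0)
    pxi = px[ii, :]
    pyj = px[jj, :]
    prod = pxi * pyj
    mask = (flat > 0) & (prod > 0)
    hxy1 = -np.where(mask, flat * np.log2(np.where(mask, prod, 1.0)), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hx > 0, (entropy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)

    out = {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "variance": variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_average": difference_average,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
    }
    return {name: v.reshape(out_shape) for name, v in out.items()}


def cooccurrence_maps(codes: np.ndarray, n_levels: int, window: int, pixel_mask=None) -> dict:
    """13 per-pixel co-occurrence metric maps for one window size.

    With a boolean ``pixel_mask``, metrics are computed only at the masked
    pixels (full-size maps are returned, zero outside the mask).
    """
    pair_codes, P = glcm_probability_stack(codes, n_levels, window, pixel_mask)
    metrics = haralick_metrics_from_stack(pair_codes, P, n_levels)
    if pixel_mask is None:
        return metrics
    mask = np.asarray(pixel_mask, dtype=bool)
    out = {}
    for name, vals in metrics.items():
        full = np.zeros(mask.shape, dtype=np.float64)
        full[mask] = vals
        out[name] = full
    return out
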