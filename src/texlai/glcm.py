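"""Gray-level co-occurrence (GLCM) texture features over sliding windows.

Eight second-order statistics per band — mean (MEA), variance (VAR),
homogeneity (HOM), contrast (CON), dissimilarity (DIS), entropy (ENT),
second/angular moment (SEM) and correlation (COR) — computed from the
normalized co-occurrence matrix P(i, j) of gray-level pairs at a fixed pixel
offset inside a small window.  A plot-level texture feature is the unweighted
mean of the per-window value over every window that fits fully inside the
raster and whose center pixel is vegetation.  With six bands this yields the
48 labeled features MEA1 … COR6 per plot.

Formulas (levels i, j in 0..G−1, u the GLCM mean, μ_i/VAR_i marginal moments):

====  =======================================================
MEA   Σ i·P(i,j)
VAR   Σ (i−u)²·P(i,j)
HOM   Σ P(i,j) / (1 + (i−j)²)
CON   Σ (i−j)²·P(i,j)
DIS   Σ |i−j|·P(i,j)
ENT   −Σ P(i,j)·log P(i,j)            (0·log 0 := 0)
SEM   Σ P(i,j)²
COR   Σ (i−μ_i)(j−μ_j)·P(i,j) / √(VAR_i·VAR_j)   (0 if degenerate)
====  =======================================================

Defaults: 7×7 window, offset (1, 1) — pixel (r, c) paired with (r+1, c+1) —
32 gray levels, symmetric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWindowError, EmptyROIError, SceneTooSmallError
from .imagery import BAND_NAMES, MultispectralImage

__all__ = [
    "GLCMConfig",
    "GLCM",
    "FEATURE_NAMES",
    "TEXTURE_LABELS",
    "TextureFeatureSet",
    "quantize_band",
    "glcm_from_window",
    "features_from_glcm",
    "window_texture_features",
    "plot_texture_features",
]

FEATURE_NAMES: tuple[str, ...] = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEM", "COR")

#: Canonical labels of the 48 plot-level texture features (feature × band 1-6).
TEXTURE_LABELS: tuple[str, ...] = tuple(
    f"{feat}{b}" for feat in FEATURE_NAMES for b in range(1, 7)
)

_EPS = 1e-12


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence settings: window size, pixel offset, gray levels."""

    window: int = 7
    offset: tuple[int, int] = (1, 1)  # (dx, dy): (r, c) vs (r+dy, c+dx)
    gray_levels: int = 32
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.offset == (0, 0):
            raise ValueError("offset must be nonzero")


@dataclass
class GLCM:
    """Normalized co-occurrence matrix P of shape (G, G)."""

    P: np.ndarray
    G: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (self.G, self.G):
            raise ValueError("P must be G x G")
        if np.any(self.P < 0) or abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("P must be a normalized probability matrix")


@dataclass
class TextureFeatureSet:
    """The 48 plot-level texture features, keyed MEA1 … COR6."""

    plot_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(TEXTURE_LABELS):
            raise ValueError("expected exactly the 48 canonical texture labels")

    def as_series(self):
        import pandas as pd

        return pd.Series({k: self.values[k] for k in TEXTURE_LABELS}, name=self.plot_id)


def quantize_band(
    band: np.ndarray, gray_levels: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Linear min–max quantization of a band to integer levels 0..G−1.

    The min/max range is taken over ``mask`` pixels when given (values outside
    the range clip to the end bins); a constant band maps to all zeros.
    """
    band = np.asarray(band, dtype=np.float64)
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")
    sel = band[np.asarray(mask, dtype=bool)] if mask is not None else band
    if sel.size == 0:
        raise EmptyROIError("mask selects no pixels for quantization")
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.int64)
    q = np.floor((band - lo) / (hi - lo) * gray_levels).astype(np.int64)
    return np.clip(q, 0, gray_levels - 1)


def glcm_from_window(window: np.ndarray, config: GLCMConfig) -> GLCM:
    """Co-occurrence matrix of one quantized window.

    Counts pairs (pixel, pixel at +offset) whose both ends lie inside the
    window; with ``symmetric`` the transposed pairs are added before
    normalizing to sum 1.
    """
    q = np.asarray(window, dtype=np.int64)
    dx, dy = config.offset
    h, w = q.shape
    if h <= abs(dy) or w <= abs(dx):
        raise DegenerateWindowError("no valid pixel pair at the offset")
    a = q[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
    b = q[max(0, dy) :, max(0, dx) :][: a.shape[0], : a.shape[1]]
    G = config.gray_levels
    counts = np.zeros((G, G), dtype=np.float64)
    np.add.at(counts, (a.ravel(), b.ravel()), 1.0)
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateWindowError("no valid pixel pair at the offset")
    return GLCM(counts / total, G)


def features_from_glcm(glcm: GLCM) -> dict[str, float]:
    """The eight texture statistics of one normalized GLCM."""
    P = glcm.P
    G = glcm.G
    lev = np.arange(G, dtype=np.float64)
    i = lev[:, None]
    j = lev[None, :]
    mea = float((i * P).sum())
    var = float(((i - mea) ** 2 * P).sum())
    hom = float((P / (1.0 + (i - j) ** 2)).sum())
    con = float(((i - j) ** 2 * P).sum())
    dis = float((np.abs(i - j) * P).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-(P * np.where(P > 0, np.log(P), 0.0)).sum())
    sem = float((P**2).sum())
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float(p_i @ lev)
    mu_j = float(p_j @ lev)
    var_i = float(p_i @ lev**2) - mu_i**2
    var_j = float(p_j @ lev**2) - mu_j**2
    if var_i <= _EPS or var_j <= _EPS:
        cor = 0.0
    else:
        cov = float(((i - mu_i) * (j - mu_j) * P).sum())
        cor = cov / np.sqrt(var_i * var_j)
    return {
        "MEA": mea,
        "VAR": var,
        "HOM": hom,
        "CON": con,
        "DIS": dis,
        "ENT": ent,
        "SEM": sem,
        "COR": cor,
    }


def _window_pair_ids(q: np.ndarray, config: GLCMConfig) -> tuple[np.ndarray, int, int]:
    """Co-occurring level-pair ids (i·G+j) per full window, row-major centers.

    Returns (ids of shape (n_windows, pairs), n_rows, n_cols).  With
    ``symmetric`` the transposed pairs are appended, so a plain mean over a
    row equals an expectation under the symmetric normalized GLCM.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    G = config.gray_levels
    dx, dy = config.offset
    win = config.window
    H, W = q.shape
    if H < win or W < win:
        raise SceneTooSmallError(f"raster {q.shape} smaller than {win}x{win} window")
    # pair anchor grid: (r, c) paired with (r+dy, c+dx)
    r0, c0 = max(0, -dy), max(0, -dx)
    a = q[r0 : H - max(0, dy), c0 : W - max(0, dx)]
    b = q[max(0, dy) :, max(0, dx) :][: a.shape[0], : a.shape[1]]
    pair_id = (a * G + b).astype(np.int32)
    ph, pw = win - abs(dy), win - abs(dx)  # pairs per window: ph*pw
    if ph <= 0 or pw <= 0:
        raise DegenerateWindowError("offset larger than window")
    wins = sliding_window_view(pair_id, (ph, pw))  # anchored at window top-left
    n_rows, n_cols = H - win + 1, W - win + 1
    ids = wins[:n_rows, :n_cols].reshape(n_rows * n_cols, ph * pw)
    if config.symmetric:
        ids = np.concatenate([ids, (ids % G) * G + ids // G], axis=1)
    return ids, n_rows, n_cols


def _features_from_ids(ids: np.ndarray, G: int) -> dict[str, np.ndarray]:
    """Vectorized eight-feature computation from per-window pair-id rows.

    Every statistic is an expectation under the window's normalized GLCM,
    i.e. a mean over the (possibly symmetrized) pair entries; only entropy
    and the second moment need the per-window pair multiplicities, obtained
    by sorting each row and run-length encoding.
    """
    n_win, m = ids.shape
    lut = np.arange(G * G, dtype=np.float64)
    li_lut, lj_lut = lut // G, lut % G
    li = li_lut[ids]
    lj = lj_lut[ids]
    d = li - lj
    mea = li.mean(axis=1)
    var = (li**2).mean(axis=1) - mea**2
    hom = (1.0 / (1.0 + d * d)).mean(axis=1)
    con = (d * d).mean(axis=1)
    dis = np.abs(d).mean(axis=1)
    mu_j = lj.mean(axis=1)
    var_j = (lj**2).mean(axis=1) - mu_j**2
    cov = (li * lj).mean(axis=1) - mea * mu_j
    denom = np.sqrt(np.maximum(var * var_j, 0.0))
    cor = np.where((var > _EPS) & (var_j > _EPS), cov / np.where(denom > 0, denom, 1.0), 0.0)
    # run-length encode sorted rows for P(i,j) multiplicities
    flat = np.sort(ids, axis=1).ravel()
    change = np.ones(flat.size, dtype=bool)
    change[1:] = flat[1:] != flat[:-1]
    change[:: m] = True  # runs never span window rows
    run_start = np.flatnonzero(change)
    run_len = np.diff(np.append(run_start, flat.size))
    row_of_run = run_start // m
    p = run_len / m
    ent = np.bincount(row_of_run, weights=-p * np.log(p), minlength=n_win)
    sem = np.bincount(row_of_run, weights=p * p, minlength=n_win)
    return {
        "MEA": mea,
        "VAR": var,
        "HOM": hom,
        "CON": con,
        "DIS": dis,
        "ENT": ent,
        "SEM": sem,
        "COR": cor,
    }


def window_texture_features(
    image: MultispectralImage,
    mask: np.ndarray,
    config: GLCMConfig = GLCMConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window texture features for every full window with a masked center.

    Returns ``(features, rows, cols)`` where ``features`` has shape
    (n_windows, 48) in :data:`TEXTURE_LABELS` order and ``rows``/``cols`` give
    the center pixel of each window.  Quantization range per band is taken
    over the masked pixels of the whole image.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    half = config.window // 2
    H, W = image.shape
    if H < config.window or W < config.window:
        raise SceneTooSmallError(f"image {image.shape} smaller than analysis window")
    center_mask = mask[half : H - half, half : W - half].ravel()
    if not center_mask.any():
        raise EmptyROIError("no full analysis window with a vegetation center")
    per_band: list[dict[str, np.ndarray]] = []
    for bi in range(6):
        q = quantize_band(image.data[:, :, bi], config.gray_levels, mask)
        ids, n_rows, n_cols = _window_pair_ids(q, config)
        per_band.append(_features_from_ids(ids[center_mask], config.gray_levels))
    n_win = int(center_mask.sum())
    out = np.empty((n_win, len(TEXTURE_LABELS)), dtype=np.float64)
    for li, label in enumerate(TEXTURE_LABELS):
        feat, band = label[:3], int(label[3:]) - 1
        out[:, li] = per_band[band][feat]
    idx = np.flatnonzero(center_mask)
    rows = idx // n_cols + half
    cols = idx % n_cols + half
    return out, rows, cols


def plot_texture_features(
    image: MultispectralImage,
    mask: np.ndarray,
    config: GLCMConfig = GLCMConfig(),
    plot_id: str = "",
) -> TextureFeatureSet:
    """Plot-level texture features: mean over windows of the per-window values."""
    feats, _, _ = window_texture_features(image, mask, config)
    means = feats.mean(axis=0)
    return TextureFeatureSet(
        plot_id, {label: float(means[i]) for i, label in enumerate(TEXTURE_LABELS)}
    )
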