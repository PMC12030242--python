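"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive co-occurrence matrices, texture statistics and
index-search optima with plain Python loops, independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import texlai


# ------------------------------------------------------------------ oracles

def brute_glcm(window: np.ndarray, offset: tuple[int, int], gray_levels: int,
               symmetric: bool) -> np.ndarray:
    """Pair-counting GLCM by explicit loops: (r, c) paired with (r+dy, c+dx)."""
    dx, dy = offset
    h, w = window.shape
    counts = np.zeros((gray_levels, gray_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[window[r, c], window[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def brute_features(P: np.ndarray) -> dict[str, float]:
    """The eight texture statistics by explicit double loops."""
    G = P.shape[0]
    mea = sum(i * P[i, j] for i in range(G) for j in range(G))
    var = sum((i - mea) ** 2 * P[i, j] for i in range(G) for j in range(G))
    hom = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    con = sum((i - j) ** 2 * P[i, j] for i in range(G) for j in range(G))
    dis = sum(abs(i - j) * P[i, j] for i in range(G) for j in range(G))
    ent = -sum(P[i, j] * math.log(P[i, j]) for i in range(G) for j in range(G)
               if P[i, j] > 0)
    sem = sum(P[i, j] ** 2 for i in range(G) for j in range(G))
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = sum(i * p_i[i] for i in range(G))
    mu_j = sum(j * p_j[j] for j in range(G))
    var_i = sum((i - mu_i) ** 2 * p_i[i] for i in range(G))
    var_j = sum((j - mu_j) ** 2 * p_j[j] for j in range(G))
    if var_i <= 1e-12 or var_j <= 1e-12:
        cor = 0.0
    else:
        cov = sum((i - mu_i) * (j - mu_j) * P[i, j] for i in range(G) for j in range(G))
        cor = cov / math.sqrt(var_i * var_j)
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con, "DIS": dis,
            "ENT": ent, "SEM": sem, "COR": cor}


def brute_plot_features(image: texlai.MultispectralImage, mask: np.ndarray,
                        config: texlai.GLCMConfig) -> dict[str, float]:
    """Plot-level 48 features by looping every full window with a masked center."""
    half = config.window // 2
    H, W = image.shape
    sums: dict[str, list[float]] = {lab: [] for lab in texlai.TEXTURE_LABELS}
    for bi in range(6):
        q = texlai.quantize_band(image.data[:, :, bi], config.gray_levels, mask)
        for r in range(half, H - half):
            for c in range(half, W - half):
                if not mask[r, c]:
                    continue
                win = q[r - half : r + half + 1, c - half : c + half + 1]
                P = brute_glcm(win, config.offset, config.gray_levels, config.symmetric)
                feats = brute_features(P)
                for name, v in feats.items():
                    sums[f"{name}{bi + 1}"].append(v)
    return {lab: float(np.mean(vals)) for lab, vals in sums.items()}


def brute_pearson(x, y) -> float:
    """Closed-form sample correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x**2).sum() - sx**2) * math.sqrt(n * (y**2).sum() - sy**2)
    return num / den


def brute_search(family: str, features: pd.DataFrame, lai: np.ndarray):
    """Exhaustive index-family search with plain loops (lexicographic labels).

    Mirrors the validity contract: >= 80% finite samples, nonconstant index.
    Returns (best_labels, best_abs_r).
    """
    fam = texlai.FAMILIES[[f.name for f in texlai.FAMILIES].index(family)]
    labels = sorted(str(c) for c in features.columns)
    cols = {l: features[l].to_numpy(float) for l in labels}
    n = len(lai)
    min_used = math.ceil(0.8 * n)
    best = (None, -1.0)
    import itertools

    for tup in itertools.product(labels, repeat=fam.arity):
        vals = fam.evaluate(*[cols[l] for l in tup])
        ok = np.isfinite(vals)
        if ok.sum() < min_used:
            continue
        v, y = vals[ok], lai[ok]
        if ((v - v.mean()) ** 2).sum() <= 1e-20 or ((y - y.mean()) ** 2).sum() <= 1e-20:
            continue
        r = abs(brute_pearson(v, y))
        if r > best[1] + 1e-15:
            best = (tup, r)
    return best


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_experiment():
    """One default 90-plot synthetic experiment with extracted feature tables."""
    samples, truth = texlai.generate_experiment(seed=42)
    config = texlai.RunConfig(generator_seed=42)
    vis, tfs = texlai.extract_features(samples, config)
    lai = truth["true_lai"].to_numpy()
    return {"samples": samples, "truth": truth, "vis": vis, "tfs": tfs, "lai": lai}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_image(rng):
    data = rng.random((11, 11, 6)).astype(np.float32)
    return texlai.MultispectralImage(data)
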