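"""Texture-index families and the exhaustive correlation-matrix search.

Eleven algebraic families combine two (T_i, T_j) or three (T_i, T_j, T_k)
texture features into a candidate index:

    arity 2:  RTI  = Ti/Tj            DTI  = Ti−Tj          ATI  = Ti+Tj
              NDTI = (Ti−Tj)/(Ti+Tj)  RDTI = 1/Ti−1/Tj      RATI = 1/Ti+1/Tj
    arity 3:  RTTI  = Ti/Tj/Tk        DTTI  = Ti−Tj−Tk
              NDTTI = (Ti−Tj−Tk)/(Ti+Tj+Tk)
              RDTTI = 1/Ti−1/Tj−1/Tk  RATTI = 1/Ti+1/Tj+1/Tk

The search evaluates a family at every ordered tuple (repetition allowed) of
the 48 texture-feature columns, correlates each candidate column with LAI
(Pearson) and reports the tuple maximizing |r|.  Tuples are enumerated in
lexicographic label order and ties resolve to the first maximum, so results
are reproducible.  Tuples whose index value is non-finite for more than 20%
of the samples, or whose index column is constant, are invalid.

Division by zero never raises: non-finite values act as invalid markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SearchFailureError, UndefinedCorrelationError

__all__ = [
    "TextureIndexFamily",
    "FAMILIES",
    "FAMILY_NAMES",
    "ti_value",
    "tti_value",
    "pearson",
    "CorrelationScreen",
    "screen_variables",
    "CombinationResult",
    "SearchTensor",
    "search_family",
    "best_combination_table",
    "materialize_index",
]

_MIN_FINITE_FRACTION = 0.8


@dataclass(frozen=True)
class TextureIndexFamily:
    """One algebraic index family: a name, an arity and a formula."""

    name: str
    arity: int

    def evaluate(self, *terms):
        """Elementwise formula evaluation; non-finite results become NaN."""
        if len(terms) != self.arity:
            raise ValueError(f"{self.name} takes {self.arity} terms")
        t = [np.asarray(x, dtype=np.float64) for x in terms]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            if self.name == "RTI":
                out = t[0] / t[1]
            elif self.name == "DTI":
                out = t[0] - t[1]
            elif self.name == "ATI":
                out = t[0] + t[1]
            elif self.name == "NDTI":
                out = (t[0] - t[1]) / (t[0] + t[1])
            elif self.name == "RDTI":
                out = 1.0 / t[0] - 1.0 / t[1]
            elif self.name == "RATI":
                out = 1.0 / t[0] + 1.0 / t[1]
            elif self.name == "RTTI":
                out = t[0] / t[1] / t[2]
            elif self.name == "DTTI":
                out = t[0] - t[1] - t[2]
            elif self.name == "NDTTI":
                out = (t[0] - t[1] - t[2]) / (t[0] + t[1] + t[2])
            elif self.name == "RDTTI":
                out = 1.0 / t[0] - 1.0 / t[1] - 1.0 / t[2]
            elif self.name == "RATTI":
                out = 1.0 / t[0] + 1.0 / t[1] + 1.0 / t[2]
            else:  # pragma: no cover - families are a closed set
                raise ValueError(f"unknown family {self.name}")
        out = np.asarray(out, dtype=np.float64)
        return np.where(np.isfinite(out), out, np.nan)


FAMILIES: tuple[TextureIndexFamily, ...] = (
    TextureIndexFamily("RTI", 2),
    TextureIndexFamily("DTI", 2),
    TextureIndexFamily("ATI", 2),
    TextureIndexFamily("NDTI", 2),
    TextureIndexFamily("RDTI", 2),
    TextureIndexFamily("RATI", 2),
    TextureIndexFamily("RTTI", 3),
    TextureIndexFamily("DTTI", 3),
    TextureIndexFamily("NDTTI", 3),
    TextureIndexFamily("RDTTI", 3),
    TextureIndexFamily("RATTI", 3),
)

FAMILY_NAMES: tuple[str, ...] = tuple(f.name for f in FAMILIES)
_BY_NAME = {f.name: f for f in FAMILIES}


def get_family(name: str) -> TextureIndexFamily:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown index family {name!r}") from None


def ti_value(family: str, ti, tj):
    """Two-term index value; NaN marks undefined results."""
    fam = get_family(family)
    if fam.arity != 2:
        raise ValueError(f"{family} is not a two-term family")
    return fam.evaluate(ti, tj)


def tti_value(family: str, ti, tj, tk):
    """Three-term index value; NaN marks undefined results."""
    fam = get_family(family)
    if fam.arity != 3:
        raise ValueError(f"{family} is not a three-term family")
    return fam.evaluate(ti, tj, tk)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p-value from the t distribution.

    ``t = r·√((n−2)/(1−r²))`` on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationScreen:
    """Screening record of one candidate variable against LAI."""

    name: str
    r: float
    p: float
    n: int
    selected: bool
    defined: bool = True


def screen_variables(
    features: pd.DataFrame, lai, alpha: float = 0.05
) -> list[CorrelationScreen]:
    """Pearson screen of every feature column; selected ⟺ p < alpha.

    Constant (or non-finite) columns are recorded as undefined and never
    selected.
    """
    y = np.asarray(lai, dtype=np.float64)
    if len(features) != len(y):
        raise ValueError("feature table and LAI vector are misaligned")
    out: list[CorrelationScreen] = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
            out.append(CorrelationScreen(str(name), np.nan, np.nan, len(y), False, False))
            continue
        r, p = pearson(x, y)
        out.append(CorrelationScreen(str(name), r, p, len(y), bool(p < alpha)))
    return out


def screen_table(screens: list[CorrelationScreen]) -> pd.DataFrame:
    """Screening results as a tidy table (variable, r, p, selected)."""
    return pd.DataFrame(
        {
            "variable": [s.name for s in screens],
            "r": [s.r for s in screens],
            "p": [s.p for s in screens],
            "selected": [s.selected for s in screens],
        }
    )


@dataclass
class CombinationResult:
    """Best tuple of one family: labels, signed r, |r|, p, samples used."""

    family: str
    labels: tuple[str, ...]
    r: float
    abs_r: float
    p: float
    n_used: int


@dataclass
class SearchTensor:
    """|r| over every ordered tuple of one family.

    ``values`` has shape (K,)*arity over ``labels`` (lexicographic order);
    invalid tuples are NaN with ``invalid`` True.
    """

    family: str
    labels: tuple[str, ...]
    values: np.ndarray
    invalid: np.ndarray


def _masked_pearson_r(X: np.ndarray, y: np.ndarray, min_used: int):
    """Row-wise Pearson r of X (m, n; NaN = missing) against y (n,).

    Returns (r, n_used, valid): r is NaN for rows with too few finite values
    or zero variance.
    """
    F = np.isfinite(X)
    nu = F.sum(axis=-1)
    Ff = F.astype(np.float64)
    Xz = np.where(F, X, 0.0)
    sy = Ff @ y
    syy = Ff @ (y * y)
    sx = Xz.sum(axis=-1)
    sxx = (Xz * Xz).sum(axis=-1)
    sxy = Xz @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        nuf = nu.astype(np.float64)
        cov = sxy - sx * sy / np.maximum(nuf, 1.0)
        varx = sxx - sx * sx / np.maximum(nuf, 1.0)
        vary = syy - sy * sy / np.maximum(nuf, 1.0)
        r = cov / np.sqrt(varx * vary)
    valid = (nu >= min_used) & (varx > 1e-20) & (vary > 1e-20) & np.isfinite(r)
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)
    return r, nu, valid


def _p_from_r(r: float, n: int) -> float:
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else float("nan")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def search_family(
    family: str, features: pd.DataFrame, lai
) -> tuple[SearchTensor, CombinationResult]:
    """Exhaustive |r|-maximizing search of one family over all ordered tuples.

    Columns are taken in lexicographic label order; every ordered tuple with
    repetition is evaluated against LAI over the samples where the index is
    finite (at least 80% of them required).  Returns the full |r| tensor and
    the arg-max tuple with its signed r and p-value.
    """
    fam = get_family(family)
    labels = tuple(sorted(str(c) for c in features.columns))
    T = features[list(labels)].to_numpy(dtype=np.float64).T  # (K, n)
    y = np.asarray(lai, dtype=np.float64)
    if T.shape[1] != len(y):
        raise ValueError("feature table and LAI vector are misaligned")
    n = len(y)
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 samples")
    K = len(labels)
    min_used = int(np.ceil(_MIN_FINITE_FRACTION * n))
    if fam.arity == 2:
        X = fam.evaluate(T[:, None, :], T[None, :, :]).reshape(K * K, n)
        r, nu, valid = _masked_pearson_r(X, y, min_used)
        r = r.reshape(K, K)
        nu = nu.reshape(K, K)
        valid = valid.reshape(K, K)
    else:
        r = np.empty((K, K, K))
        nu = np.empty((K, K, K), dtype=np.int64)
        valid = np.empty((K, K, K), dtype=bool)
        for a in range(K):
            X = fam.evaluate(
                T[a][None, None, :], T[:, None, :], T[None, :, :]
            ).reshape(K * K, n)
            ra, na, va = _masked_pearson_r(X, y, min_used)
            r[a] = ra.reshape(K, K)
            nu[a] = na.reshape(K, K)
            valid[a] = va.reshape(K, K)
    abs_r = np.abs(r)
    if not valid.any():
        raise SearchFailureError(f"{family}: every tuple is invalid")
    flat = np.where(valid.ravel(), abs_r.ravel(), -np.inf)
    best = int(np.argmax(flat))  # first max = lexicographic tie-break
    idx = np.unravel_index(best, (K,) * fam.arity)
    best_labels = tuple(labels[i] for i in idx)
    best_r = float(r[idx])
    best_n = int(nu[idx])
    tensor = SearchTensor(family, labels, abs_r, ~valid)
    result = CombinationResult(
        family, best_labels, best_r, abs(best_r), _p_from_r(best_r, best_n), best_n
    )
    return tensor, result


def best_combination_table(
    features: pd.DataFrame, lai, families=FAMILY_NAMES
) -> pd.DataFrame:
    """Best tuple per family, one row each (the optimum-combination table)."""
    rows = []
    for name in families:
        _, res = search_family(name, features, lai)
        rows.append(
            {
                "family": res.family,
                "abs_r": res.abs_r,
                "r": res.r,
                "p": res.p,
                "significant": res.p < 0.05,
                "combination": ", ".join(res.labels),
                "n_used": res.n_used,
            }
        )
    return pd.DataFrame(rows)


def materialize_index(
    family: str, features: pd.DataFrame, labels: tuple[str, ...]
) -> np.ndarray:
    """Evaluate one family at a fixed label tuple for every sample row."""
    fam = get_family(family)
    cols = [features[l].to_numpy(dtype=np.float64) for l in labels]
    return fam.evaluate(*cols)
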