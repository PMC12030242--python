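"""LAI estimation models, the input-combination grid, and inversion maps.

Three regressors are compared: a polynomial-kernel support vector machine
(C = 20, gamma = 0.02), partial least squares regression with the latent-variable
count chosen by a 5-percentage-point gain rule on cross-validated explained
Y-variance, and gradient-boosted trees (XGBoost, 100 estimators, learning
rate 0.03, depth 5).  Inputs are drawn from four feature blocks — screened
vegetation indices (VIs), screened texture features (TFs), the six best
two-term texture indices (TIs) and the five best three-term texture indices
(TTIs) — giving the 15 non-empty block combinations of the evaluation grid
(15 × 3 = 45 cells).

Data are split 2/3 modeling : 1/3 validation by a uniform random draw; one
split is shared across all cells.  Metrics: R² = 1 − SSres/SStot, RMSE, and
MRE = mean |y−ŷ|/y in percent.  Scalers are always fitted on the modeling
set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ContractError, DegenerateInputError, TooFewSamplesError
from .glcm import GLCMConfig, window_texture_features
from .imagery import MultispectralImage
from .indices import VI_NAMES, compute_vis
from .search import materialize_index

__all__ = [
    "SplitAssignment",
    "split_dataset",
    "ModelSpec",
    "MODEL_NAMES",
    "default_model_specs",
    "FittedModel",
    "fit_predict",
    "fit_model",
    "EvalMetrics",
    "evaluate",
    "InputCombination",
    "enumerate_combinations",
    "GridResult",
    "run_grid",
    "grid_table",
    "predict_map",
]

MODEL_NAMES: tuple[str, ...] = ("SVM", "PLSR", "XGBoost")

BLOCK_NAMES: tuple[str, ...] = ("VIs", "TFs", "TIs", "TTIs")

#: The 15 non-empty block subsets, in grid order.
_COMBINATION_ORDER: tuple[tuple[str, ...], ...] = (
    ("VIs",),
    ("TFs",),
    ("TIs",),
    ("TTIs",),
    ("VIs", "TFs"),
    ("VIs", "TIs"),
    ("VIs", "TTIs"),
    ("TFs", "TIs"),
    ("TFs", "TTIs"),
    ("TIs", "TTIs"),
    ("VIs", "TFs", "TIs"),
    ("VIs", "TFs", "TTIs"),
    ("VIs", "TIs", "TTIs"),
    ("TFs", "TIs", "TTIs"),
    ("VIs", "TFs", "TIs", "TTIs"),
)


@dataclass
class SplitAssignment:
    """Modeling/validation partition of sample ids."""

    modeling: np.ndarray
    validation: np.ndarray
    seed: int


def split_dataset(n_samples: int, fraction: float = 2.0 / 3.0, seed: int = 0) -> SplitAssignment:
    """Random 2/3 : 1/3 split (modeling size = floor(fraction·n))."""
    if n_samples < 3:
        raise TooFewSamplesError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_model = int(np.floor(fraction * n_samples))
    return SplitAssignment(np.sort(perm[:n_model]), np.sort(perm[n_model:]), seed)


@dataclass(frozen=True)
class ModelSpec:
    """A named regressor with its pinned hyperparameters."""

    name: str
    svm_C: float = 20.0
    svm_gamma: float = 0.02
    svm_degree: int = 3
    pls_max_lv: int = 10
    pls_gain_threshold: float = 5.0  # percentage points of explained Y-variance
    xgb_n_estimators: int = 100
    xgb_learning_rate: float = 0.03
    xgb_max_depth: int = 5
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")


def default_model_specs(random_state: int = 0) -> tuple[ModelSpec, ...]:
    return tuple(ModelSpec(name, random_state=random_state) for name in MODEL_NAMES)


def _select_pls_components(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec
) -> int:
    """Latent-variable count by the sequential 5%-gain rule.

    Cumulative explained Y-variance is estimated as 100·CV-R² with k
    components (5-fold, shuffled with a fixed seed); component k+1 is kept
    only while it adds at least ``pls_gain_threshold`` percentage points.
    """
    n, p = X.shape
    cap = max(1, min(spec.pls_max_lv, p, n - 2))
    n_folds = min(5, n)
    if n_folds < 2:
        return 1
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=spec.random_state)

    def cv_explained(k: int) -> float:
        press, sstot = 0.0, 0.0
        for tr, te in kf.split(X):
            keff = max(1, min(k, len(tr) - 1))
            pls = PLSRegression(n_components=keff, scale=False)
            pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
            press += float(((y[te] - pred) ** 2).sum())
            sstot += float(((y[te] - y[tr].mean()) ** 2).sum())
        return 100.0 * (1.0 - press / sstot) if sstot > 0 else 0.0

    k = 1
    ev = cv_explained(1)
    while k < cap:
        ev_next = cv_explained(k + 1)
        if ev_next - ev >= spec.pls_gain_threshold:
            k += 1
            ev = ev_next
        else:
            break
    return k


@dataclass
class FittedModel:
    """A trained regressor plus its train-only scaler and provenance."""

    spec: ModelSpec
    estimator: object
    scaler: StandardScaler | None
    n_features: int
    combination: str = ""
    constant_y: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ContractError(
                f"expected {self.n_features} feature columns, got {X.shape}"
            )
        if self.constant_y is not None:
            return np.full(X.shape[0], self.constant_y)
        Xs = self.scaler.transform(X) if self.scaler is not None else X
        return np.asarray(self.estimator.predict(Xs), dtype=np.float64).ravel()


def fit_model(spec: ModelSpec, X_train: np.ndarray, y_train: np.ndarray) -> FittedModel:
    """Fit one regressor; scalers (SVM, PLSR) are fitted on training data only."""
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if X_train.ndim != 2 or len(X_train) != len(y_train):
        raise ValueError("X_train must be 2-D and aligned with y_train")
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(y_train))):
        raise DegenerateInputError("missing values in training data")
    if np.all(np.ptp(X_train, axis=0) == 0):
        raise DegenerateInputError("all feature columns are constant")
    if np.ptp(y_train) == 0:
        return FittedModel(spec, None, None, X_train.shape[1],
                           constant_y=float(y_train[0]))
    if spec.name == "SVM":
        scaler = StandardScaler().fit(X_train)
        est = SVR(kernel="poly", C=spec.svm_C, gamma=spec.svm_gamma,
                  degree=spec.svm_degree)
        est.fit(scaler.transform(X_train), y_train)
        return FittedModel(spec, est, scaler, X_train.shape[1])
    if spec.name == "PLSR":
        scaler = StandardScaler().fit(X_train)
        Xs = scaler.transform(X_train)
        k = _select_pls_components(Xs, y_train, spec)
        est = PLSRegression(n_components=k, scale=False)
        est.fit(Xs, y_train)
        return FittedModel(spec, est, scaler, X_train.shape[1])
    # XGBoost: trees are scale-equivariant, no standardization needed
    from xgboost import XGBRegressor

    est = XGBRegressor(
        n_estimators=spec.xgb_n_estimators,
        learning_rate=spec.xgb_learning_rate,
        max_depth=spec.xgb_max_depth,
        random_state=spec.random_state,
        n_jobs=1,
        verbosity=0,
    )
    est.fit(X_train, y_train)
    return FittedModel(spec, est, None, X_train.shape[1])


def fit_predict(
    spec: ModelSpec, X_train: np.ndarray, y_train: np.ndarray, X_eval: np.ndarray
) -> np.ndarray:
    """Fit on the training rows and predict the evaluation rows."""
    return fit_model(spec, X_train, y_train).predict(np.asarray(X_eval, dtype=np.float64))


@dataclass
class EvalMetrics:
    """R², RMSE (LAI units) and MRE (%) of a prediction set."""

    r2: float
    rmse: float
    mre: float


def evaluate(y_true, y_pred) -> EvalMetrics:
    """R² = 1−SSres/SStot, RMSE = √(mean squared error), MRE = mean |e|/y in %.

    R² is NaN (undefined) when y_true has zero variance; MRE requires
    strictly positive y_true.
    """
    y = np.asarray(y_true, dtype=np.float64)
    yhat = np.asarray(y_pred, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if np.any(y <= 0):
        raise ValueError("MRE requires strictly positive y_true")
    res = y - yhat
    ss_res = float((res**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt((res**2).mean()))
    mre = float(100.0 * np.abs(res / y).mean())
    return EvalMetrics(r2, rmse, mre)


@dataclass
class InputCombination:
    """A named subset of feature blocks resolved to concrete columns."""

    name: str
    blocks: tuple[str, ...]
    columns: list[str]


def enumerate_combinations(block_columns: dict[str, list[str]]) -> list[InputCombination]:
    """The 15 non-empty block subsets with their resolved feature columns.

    ``block_columns`` maps each of VIs/TFs/TIs/TTIs to its column names.
    """
    missing = set(BLOCK_NAMES) - set(block_columns)
    if missing:
        raise ValueError(f"missing blocks: {sorted(missing)}")
    out = []
    for blocks in _COMBINATION_ORDER:
        cols: list[str] = []
        for b in blocks:
            cols.extend(block_columns[b])
        out.append(InputCombination(" + ".join(blocks), blocks, cols))
    return out


@dataclass
class GridResult:
    """Metrics of one combination × model cell."""

    combination: str
    model: str
    modeling: EvalMetrics
    validation: EvalMetrics


def run_grid(
    features: pd.DataFrame,
    lai,
    block_columns: dict[str, list[str]],
    split: SplitAssignment,
    specs: tuple[ModelSpec, ...] | None = None,
) -> list[GridResult]:
    """Fit and score every combination × model cell on one shared split."""
    specs = specs if specs is not None else default_model_specs()
    y = np.asarray(lai, dtype=np.float64)
    if len(features) != len(y):
        raise ValueError("feature table and LAI vector are misaligned")
    combos = enumerate_combinations(block_columns)
    results: list[GridResult] = []
    for combo in combos:
        X = features[combo.columns].to_numpy(dtype=np.float64)
        Xtr, ytr = X[split.modeling], y[split.modeling]
        Xva, yva = X[split.validation], y[split.validation]
        for spec in specs:
            model = fit_model(spec, Xtr, ytr)
            results.append(
                GridResult(
                    combo.name,
                    spec.name,
                    evaluate(ytr, model.predict(Xtr)),
                    evaluate(yva, model.predict(Xva)),
                )
            )
    return results


def grid_table(results: list[GridResult]) -> pd.DataFrame:
    """Grid results as a tidy table, one row per cell."""
    return pd.DataFrame(
        {
            "combination": [g.combination for g in results],
            "model": [g.model for g in results],
            "modeling_R2": [g.modeling.r2 for g in results],
            "modeling_RMSE": [g.modeling.rmse for g in results],
            "modeling_MRE_pct": [g.modeling.mre for g in results],
            "validation_R2": [g.validation.r2 for g in results],
            "validation_RMSE": [g.validation.rmse for g in results],
            "validation_MRE_pct": [g.validation.mre for g in results],
        }
    )


def predict_map(
    image: MultispectralImage,
    mask: np.ndarray,
    model: FittedModel,
    combination: InputCombination,
    best_tuples: dict[str, tuple[str, ...]] | None = None,
    glcm_config: GLCMConfig = GLCMConfig(),
) -> np.ndarray:
    """Per-pixel LAI raster from sliding-window features.

    Every masked pixel whose analysis window fits inside the raster gets a
    prediction from features computed on its own window: VIs from the window
    mean reflectance, texture features from the window GLCMs, and texture
    indices from those features at the training-time best tuples
    (``best_tuples`` maps family name → label tuple; required when the
    combination uses TIs or TTIs).  Other pixels are NaN (no-data).
    """
    needs_ti = any(b in combination.blocks for b in ("TIs", "TTIs"))
    if needs_ti and not best_tuples:
        raise ContractError("combination uses texture indices but no best_tuples given")
    tf, rows, cols = window_texture_features(image, mask, glcm_config)
    from .glcm import TEXTURE_LABELS

    table = pd.DataFrame(tf, columns=list(TEXTURE_LABELS))
    # window-mean reflectance per band via a uniform filter
    from scipy.ndimage import uniform_filter

    if "VIs" in combination.blocks or any(c in VI_NAMES for c in combination.columns):
        from .imagery import ReflectanceRecord

        means = [
            uniform_filter(image.data[:, :, b].astype(np.float64), glcm_config.window)
            for b in range(6)
        ]
        vi_rows = []
        for r, c in zip(rows, cols):
            rec = ReflectanceRecord("", *[float(m[r, c]) for m in means])
            vi_rows.append(compute_vis(rec).values)
        vi_tab = pd.DataFrame(vi_rows)
        for name in vi_tab.columns:
            table[name] = vi_tab[name].to_numpy()
    if best_tuples:
        for fam, labels in best_tuples.items():
            table[f"{fam}_best"] = materialize_index(fam, table, labels)
    missing = [c for c in combination.columns if c not in table.columns]
    if missing:
        raise ContractError(f"combination columns not derivable per-pixel: {missing}")
    X = table[combination.columns].to_numpy(dtype=np.float64)
    ok = np.all(np.isfinite(X), axis=1)
    out = np.full(image.shape, np.nan)
    if ok.any():
        # LAI is non-negative; clamp linear-model excursions at extreme windows
        out[rows[ok], cols[ok]] = np.maximum(model.predict(X[ok]), 0.0)
    return out
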