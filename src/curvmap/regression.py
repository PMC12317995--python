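"""Feature filtering, exhaustive 3-feature combination search with LOOCV,
and permutation analysis for aggregation-rate regression.

The protocol mirrors small-n (n ≈ 20 molecules) practice: features are first
screened by marginal Pearson correlation with the response (|r| ≥ 0.4,
p < 0.05, two-sided t-test with n−2 degrees of freedom) and by a 3σ outlier
rule; every C(m, 3) combination of the survivors is then evaluated by
leave-one-out cross-validation under one of five regressors, ranked by
out-of-sample Pearson r (ties: MSE, then feature names).  For the linear
model the LOOCV residuals are computed exactly through the hat-matrix
identity e_i/(1 − h_ii) — identical to refitting n times, but vectorizable
across thousands of combinations.

The permutation analysis shuffles the response with controlled "degree"
(Pearson correlation between original and permuted vector) and retrains the
fixed best combination for each vector, exposing how performance decays as
the signal is scrambled — the standard guard against overfitting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySelectionError, MetricError, ParameterError
from .features import FeatureTable

logger = logging.getLogger(__name__)

MODEL_KINDS = ("Linear", "KNN", "SVM", "RF", "GRB")


@dataclass
class StudyDataset:
    """A molecule × feature matrix plus the measured aggregation rates.

    Rates are stored on the 10⁻⁴ mL/(mg·week) scale (the scale the data are
    plotted on); MSE is therefore on that squared scale.
    """

    X: pd.DataFrame
    y: np.ndarray
    rate_scale: str = "1e-4 mL/mg/week"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.X):
            raise ParameterError("y length != number of molecules")
        if not np.all(np.isfinite(self.y)):
            raise ParameterError("y must be finite")

    @property
    def molecules(self) -> list:
        return list(self.X.index)

    def drop_response_outliers(self, sigma: float = 3.0) -> "StudyDataset":
        """Optional pre-filter removing molecules whose rate lies beyond
        ``sigma`` standard deviations of the mean (e.g. extreme aggregators
        that regression models cannot represent)."""
        mu, sd = self.y.mean(), self.y.std()
        keep = np.abs(self.y - mu) <= sigma * sd if sd > 0 else np.ones_like(self.y, bool)
        if not keep.all():
            logger.info("dropping %d response outlier(s)", int((~keep).sum()))
        return StudyDataset(self.X.loc[keep], self.y[keep], self.rate_scale)


@dataclass(frozen=True)
class ModelSpec:
    """A regressor family with documented default hyperparameters."""

    kind: str
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}")

    def build(self):
        """Instantiate the scikit-learn estimator (scaling included for the
        distance/kernel models so no fold leaks statistics)."""
        from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
        from sklearn.linear_model import LinearRegression
        from sklearn.neighbors import KNeighborsRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR

        if self.kind == "Linear":
            return LinearRegression()
        if self.kind == "KNN":
            return make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=3))
        if self.kind == "SVM":
            return make_pipeline(StandardScaler(), SVR(kernel="rbf", C=1.0, epsilon=0.1))
        if self.kind == "RF":
            return RandomForestRegressor(n_estimators=500, random_state=self.random_state)
        return GradientBoostingRegressor(
            n_estimators=500, learning_rate=0.1, max_depth=2,
            random_state=self.random_state,
        )


@dataclass
class EvalResult:
    """LOOCV (out-of-fold) and in-sample metrics for one feature combination."""

    combo: tuple[str, ...]
    model: str
    r: float
    r2: float
    mse: float
    r_in: float
    r2_in: float
    mse_in: float
    predictions: np.ndarray | None = None

    def sort_key(self):
        return (-self.r, self.mse, self.combo)


@dataclass
class PermutationResult:
    """Degree-of-permutation curve: per permuted response vector, its degree
    and the in-/out-of-sample R² of the retrained fixed combination."""

    table: pd.DataFrame  # columns: degree, r2_in, r2_oof, is_identity
    combo: tuple[str, ...]
    model: str
    seed: int | None = None


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise MetricError("response has zero variance")
    if np.std(yhat) == 0:
        r = 0.0  # correlation undefined for constant predictions
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    ss_res = float(((y - yhat) ** 2).sum())
    return r, 1.0 - ss_res / ss_tot, ss_res / len(y)


# ---------------------------------------------------------------------------
# Feature filtering
# ---------------------------------------------------------------------------


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t distribution, n−2 dof)."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def filter_features(
    dataset: StudyDataset,
    r_min: float = 0.4,
    p_max: float = 0.05,
    sigma: float = 3.0,
) -> list[str]:
    """Screen columns: drop constants, drop columns with any value beyond
    ``sigma`` SDs of the column mean, keep |r| ≥ r_min with p < p_max."""
    if len(dataset.y) < 3:
        raise ParameterError("need at least 3 molecules")
    retained = []
    y = dataset.y
    for col in dataset.X.columns:
        x = dataset.X[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            logger.debug("dropping %r: non-finite values", col)
            continue
        sd = x.std()
        if sd == 0:
            continue  # correlation undefined
        if np.any(np.abs(x - x.mean()) > sigma * sd):
            continue
        r, p = pearson_with_p(x, y)
        if abs(r) >= r_min and p < p_max:
            retained.append(col)
    if not retained:
        raise EmptySelectionError(
            "no feature passed the correlation/outlier filters"
        )
    return retained


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def linear_loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact OLS leave-one-out predictions via the hat-matrix identity."""
    A = _design(np.asarray(X, dtype=float))
    G = A.T @ A
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    beta = Ginv @ (A.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,jk,ik->i", A, Ginv, A)
    h = np.clip(h, None, 1.0 - 1e-12)
    return y - resid / (1.0 - h)


def brute_force_loocv_predictions(X: np.ndarray, y: np.ndarray, model_spec: ModelSpec) -> np.ndarray:
    """Refit-per-fold LOOCV (the general path; also the oracle for Linear)."""
    n = len(y)
    yhat = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = model_spec.build()
        est.fit(X[mask], y[mask])
        yhat[i] = est.predict(X[i : i + 1])[0]
    return yhat


def loocv_evaluate(
    dataset: StudyDataset,
    combo: tuple[str, ...],
    model_spec: ModelSpec,
    fast_linear: bool = True,
) -> EvalResult:
    """Fit on n−1, predict the held-out molecule, pool the n out-of-fold
    predictions into r/R²/MSE; in-sample metrics from a full-data fit."""
    if len(dataset.y) < 3:
        raise ParameterError("need at least 3 molecules")
    X = dataset.X[list(combo)].to_numpy(dtype=float)
    y = dataset.y
    if fast_linear and model_spec.kind == "Linear":
        yhat = linear_loocv_predictions(X, y)
    else:
        yhat = brute_force_loocv_predictions(X, y, model_spec)
    r, r2, mse = _metrics(y, yhat)
    est = model_spec.build()
    est.fit(X, y)
    yin = est.predict(X)
    r_in, r2_in, mse_in = _metrics(y, yin)
    return EvalResult(
        combo=tuple(combo), model=model_spec.kind,
        r=r, r2=r2, mse=mse, r_in=r_in, r2_in=r2_in, mse_in=mse_in,
        predictions=yhat,
    )


# ---------------------------------------------------------------------------
# Combination search
# ---------------------------------------------------------------------------


def _batched_linear_search(
    X: np.ndarray, y: np.ndarray, combos: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOOCV r/R²/MSE for every combo under OLS, fully vectorized."""
    n = len(y)
    A = np.concatenate(
        [np.ones((len(combos), n, 1)), np.swapaxes(X[:, combos], 0, 1)], axis=2
    )  # (ncombo, n, k+1)
    G = np.einsum("cni,cnj->cij", A, A)
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    beta = np.einsum("cij,cnj,n->ci", Ginv, A, y)
    pred = np.einsum("cni,ci->cn", A, beta)
    resid = y[None, :] - pred
    h = np.einsum("cni,cij,cnj->cn", A, Ginv, A)
    h = np.clip(h, None, 1.0 - 1e-12)
    yhat = y[None, :] - resid / (1.0 - h)

    ss_tot = float(((y - y.mean()) ** 2).sum())
    d = yhat - yhat.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((d * d).sum(axis=1) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (d @ yc) / denom
    r = np.where(denom == 0, 0.0, r)
    ss_res = ((y[None, :] - yhat) ** 2).sum(axis=1)
    return r, 1.0 - ss_res / ss_tot, ss_res / n


def combination_search(
    dataset: StudyDataset,
    retained: list[str],
    model_spec: ModelSpec,
    k: int = 3,
    top: int | None = None,
) -> list[EvalResult]:
    """Evaluate every C(m, k) combination of retained features by LOOCV and
    rank by out-of-sample r (descending), ties by MSE then feature names."""
    if len(retained) < k:
        raise ParameterError(f"need at least {k} retained features, have {len(retained)}")
    combos = list(itertools.combinations(range(len(retained)), k))
    names = list(retained)
    if model_spec.kind == "Linear":
        X = dataset.X[names].to_numpy(dtype=float)
        y = dataset.y
        r, r2, mse = _batched_linear_search(X, y, np.asarray(combos))
        results = [
            EvalResult(
                combo=tuple(names[j] for j in combo), model="Linear",
                r=float(r[i]), r2=float(r2[i]), mse=float(mse[i]),
                r_in=np.nan, r2_in=np.nan, mse_in=np.nan,
            )
            for i, combo in enumerate(combos)
        ]
    else:
        results = [
            loocv_evaluate(dataset, tuple(names[j] for j in combo), model_spec)
            for combo in combos
        ]
    results.sort(key=EvalResult.sort_key)
    if top is not None:
        results = results[:top]
    # fill in-sample metrics for the reported head of a linear search
    if model_spec.kind == "Linear":
        head = results if top is not None else results[: min(len(results), 50)]
        for res in head:
            full = loocv_evaluate(dataset, res.combo, model_spec)
            res.r_in, res.r2_in, res.mse_in = full.r_in, full.r2_in, full.mse_in
    return results


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [res.model for res in results],
            "r": [res.r for res in results],
            "R2": [res.r2 for res in results],
            "MSE": [res.mse for res in results],
            "r_in": [res.r_in for res in results],
            "R2_in": [res.r2_in for res in results],
            "MSE_in": [res.mse_in for res in results],
            "combo": ["; ".join(res.combo) for res in results],
        }
    )


# ---------------------------------------------------------------------------
# Permutation analysis
# ---------------------------------------------------------------------------


def _swap_ladder(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    perm = np.arange(len(y))
    for _ in range(k):
        i, j = rng.integers(0, len(y), size=2)
        perm[i], perm[j] = perm[j], perm[i]
    return y[perm]


def generate_permuted_responses(
    y: np.ndarray, n_vectors: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Permuted copies of y spanning a range of degrees.

    Pure random permutations cluster near degree 0, so the set mixes swap
    ladders started from the identity (k = 1..n random pairwise swaps, so
    degrees decay from +1) with full random shuffles (degrees around 0,
    occasionally negative).  The first vector is always the identity
    reference.
    """
    n = len(y)
    vectors = [y.copy()]
    k = 1
    while len(vectors) < n_vectors and k <= 4 * n:
        vectors.append(_swap_ladder(y, 1 + (k - 1) % n, rng))
        k += 1
    while len(vectors) < n_vectors:
        vectors.append(rng.permutation(y))
    return vectors


def permutation_analysis(
    dataset: StudyDataset,
    combo: tuple[str, ...],
    model_spec: ModelSpec,
    n_vectors: int = 100,
    seed: int | None = None,
) -> PermutationResult:
    """Retrain the fixed combination on permuted responses and record the
    degree-of-permutation vs in-/out-of-sample R² curve."""
    rng = np.random.default_rng(seed)
    y = dataset.y
    vectors = generate_permuted_responses(y, n_vectors, rng)
    rows = []
    for idx, y_perm in enumerate(vectors):
        degree = float(np.corrcoef(y, y_perm)[0, 1]) if np.std(y_perm) > 0 else 0.0
        perm_ds = StudyDataset(dataset.X, y_perm, dataset.rate_scale)
        try:
            res = loocv_evaluate(perm_ds, combo, model_spec)
            r2_oof, r2_in = res.r2, res.r2_in
        except MetricError:
            r2_oof = r2_in = np.nan
        rows.append(
            {
                "degree": degree,
                "r2_in": r2_in,
                "r2_oof": r2_oof,
                "is_identity": idx == 0,
            }
        )
    return PermutationResult(
        table=pd.DataFrame(rows), combo=tuple(combo), model=model_spec.kind, seed=seed
    )


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def load_study(features_csv, rates_csv) -> StudyDataset:
    """Join a feature-table CSV with a rates CSV (molecule_id, rate)."""
    ft = FeatureTable.from_csv(features_csv)
    rates = pd.read_csv(rates_csv).set_index("molecule_id")["rate"]
    common = [m for m in ft.table.index if m in rates.index]
    if not common:
        raise ParameterError("no molecule ids shared between features and rates")
    return StudyDataset(X=ft.table.loc[common], y=rates.loc[common].to_numpy())
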