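"""Decision-tree and gradient-boosting regression of ripening indicators.

Indices (features) are regressed against a trait with leave-one-out
cross-validation (LOOCV): each of the n samples is predicted by a model
trained on the remaining n - 1, and the cross-validated R²/RMSE are
computed once on the pooled out-of-fold prediction vector.  Hyperparameters
are chosen by exhaustive enumeration of small, fixed grids, minimizing
LOOCV RMSE:

* gradient boosting (GBR): boosting stages Ns in {5, 10, 15, 20, 25} and
  features-per-split Mf in {all, sqrt, log2} (learning rate 0.1,
  squared-error loss, tree depth 3 fixed);
* decision tree (DT): max depth Md in {1, 3, 5, 7, 9}, min samples per
  leaf Ms in {2, 4, 6, 8, 10}, max leaf nodes Mln in {unbounded, 10, 20,
  30, 40, 50}, with the pruning constant ccp_alpha fixed at 1e-6.

Hybrid-index fusion is greedy forward selection: starting from the empty
set, repeatedly add the candidate index whose addition (with
hyperparameters re-tuned) most lowers LOOCV RMSE, stopping at no
improvement or a size cap.

The statsmodels-style front end is :class:`SRIRegression` /
:class:`SRIRegressionResults`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.tree import DecisionTreeRegressor

from .groupstats import significance_stars

ModelKind = Literal["dt", "gbr"]


# ---------------------------------------------------------------------------
# metrics

def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error over the paired observations."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if a.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - RSS/TSS (negative for poor fits)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    tss = float(np.sum((a - a.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in actual values")
    rss = float(np.sum((a - p) ** 2))
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# model specs and grids

@dataclass(frozen=True)
class GBRSpec:
    n_estimators: int = 25
    max_features: str | None = None      # None = all, else "sqrt"/"log2"
    learning_rate: float = 0.1
    max_depth: int = 3
    random_state: int = 0

    def build(self) -> GradientBoostingRegressor:
        return GradientBoostingRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            loss="squared_error",
            random_state=self.random_state,
        )

    def label(self) -> str:
        mf = self.max_features if self.max_features else "None"
        return f"({self.n_estimators}, {mf})"

    def complexity(self) -> tuple:
        order = {None: 0, "sqrt": 1, "log2": 2}
        return (self.n_estimators, order[self.max_features])


@dataclass(frozen=True)
class DTSpec:
    max_depth: int = 5
    min_samples_leaf: int = 2
    max_leaf_nodes: int | None = None
    ccp_alpha: float = 1e-6
    random_state: int = 0

    def build(self) -> DecisionTreeRegressor:
        return DecisionTreeRegressor(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_leaf_nodes=self.max_leaf_nodes,
            ccp_alpha=self.ccp_alpha,
            random_state=self.random_state,
        )

    def label(self) -> str:
        mln = self.max_leaf_nodes if self.max_leaf_nodes else "none"
        return f"({self.max_depth}, {self.min_samples_leaf}, {mln})"

    def complexity(self) -> tuple:
        mln = math.inf if self.max_leaf_nodes is None else self.max_leaf_nodes
        return (self.max_depth, -self.min_samples_leaf, mln)


GBR_NS = (5, 10, 15, 20, 25)
GBR_MF = (None, "sqrt", "log2")
DT_MD = (1, 3, 5, 7, 9)
DT_MS = (2, 4, 6, 8, 10)
DT_MLN = (None, 10, 20, 30, 40, 50)


def default_grid(kind: ModelKind, seed: int = 0) -> list[GBRSpec] | list[DTSpec]:
    """The fixed hyperparameter grid for one model kind."""
    if kind == "gbr":
        return [GBRSpec(ns, mf, random_state=seed)
                for ns in GBR_NS for mf in GBR_MF]
    if kind == "dt":
        return [DTSpec(md, ms, mln, random_state=seed)
                for md in DT_MD for ms in DT_MS for mln in DT_MLN]
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# LOOCV machinery

def _check_xy(features, target) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and target must align")
    if X.shape[0] < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.ptp(y) == 0:
        raise ValueError("target has zero variance")
    return X, y


def loocv_evaluate(features: pd.DataFrame | np.ndarray, target: np.ndarray,
                   spec: GBRSpec | DTSpec) -> tuple[float, float, np.ndarray]:
    """Leave-one-out evaluation: (cv_R², cv_RMSE, out-of-fold predictions)."""
    X, y = _check_xy(features, target)
    n = X.shape[0]
    oof = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            est = spec.build().fit(X[mask], y[mask])
        except Exception as exc:
            raise RuntimeError(f"model training failed on fold {i}: {exc}") from exc
        oof[i] = est.predict(X[i:i + 1])[0]
        mask[i] = True
    return r_squared(y, oof), rmse(y, oof), oof


def _loocv_oof_staged(X: np.ndarray, y: np.ndarray, base: GBRSpec,
                      stage_counts: Sequence[int]) -> dict[int, np.ndarray]:
    """Out-of-fold GBR predictions for several boosting-stage counts at once.

    Boosting is sequential, so a model truncated after k stages equals a
    model trained with k stages (same random state); one fit per fold at
    max(stage_counts) yields every smaller count via staged prediction.
    """
    counts = sorted(stage_counts)
    big = dataclasses.replace(base, n_estimators=counts[-1])
    n = X.shape[0]
    oof = {k: np.empty(n) for k in counts}
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        est = big.build().fit(X[mask], y[mask])
        stages = list(est.staged_predict(X[i:i + 1]))
        for k in counts:
            oof[k][i] = stages[k - 1][0]
        mask[i] = True
    return oof


def tune_hyperparameters(features, target,
                         grid: Sequence[GBRSpec] | Sequence[DTSpec]
                         ) -> tuple[GBRSpec | DTSpec, float]:
    """Full grid enumeration; winner = minimum LOOCV RMSE.

    Ties go to the simpler model (smaller Ns; smaller Md, larger Ms,
    smaller Mln with "unbounded" counting as largest).  GBR grids that
    differ only in the boosting-stage count share one fit per fold via
    staged prediction — an exact shortcut, not an approximation.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    results: list[tuple[float, tuple, GBRSpec | DTSpec]] = []
    if all(isinstance(s, GBRSpec) for s in grid):
        X, y = _check_xy(features, target)
        groups: dict[GBRSpec, list[GBRSpec]] = {}
        for s in grid:
            groups.setdefault(dataclasses.replace(s, n_estimators=0), []).append(s)
        for specs in groups.values():
            oof = _loocv_oof_staged(X, y, specs[0],
                                    [s.n_estimators for s in specs])
            for s in specs:
                results.append((rmse(y, oof[s.n_estimators]), s.complexity(), s))
    else:
        for s in grid:
            _, cv_rmse, _ = loocv_evaluate(features, target, s)
            results.append((cv_rmse, s.complexity(), s))
    best = min(results, key=lambda t: (t[0], t[1]))
    return best[2], best[0]


# ---------------------------------------------------------------------------
# greedy forward feature fusion

def select_feature_subset(candidates: pd.DataFrame, target: np.ndarray,
                          kind: ModelKind, max_size: int,
                          grid: Sequence[GBRSpec] | Sequence[DTSpec] | None = None,
                          seed: int = 0) -> tuple[list[str], GBRSpec | DTSpec, float]:
    """Greedy forward selection of a hybrid index subset.

    Returns ``(feature_names, best_spec, best_cv_rmse)``.  At each step the
    candidate whose addition most lowers LOOCV RMSE (hyperparameters
    re-tuned per evaluation) joins the subset; ties break by candidate
    order.  Stops when nothing improves or ``max_size`` is reached.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    grid = grid if grid is not None else default_grid(kind, seed=seed)
    chosen: list[str] = []
    best_rmse = math.inf
    best_spec: GBRSpec | DTSpec | None = None
    remaining = list(candidates.columns)
    while remaining and len(chosen) < max_size:
        step_best = None
        for name in remaining:
            spec, cv_rmse = tune_hyperparameters(
                candidates[chosen + [name]], target, grid)
            if step_best is None or cv_rmse < step_best[0]:
                step_best = (cv_rmse, name, spec)
        if step_best is None or step_best[0] >= best_rmse:
            break
        best_rmse, picked, best_spec = step_best
        chosen.append(picked)
        remaining.remove(picked)
    if best_spec is None:  # single candidate never improved on inf: impossible
        raise RuntimeError("selection failed to evaluate any candidate")
    return chosen, best_spec, best_rmse


#: hybrid-index presets: the report-table feature sets, by (kind, trait).
#: Names pass through the registry alias map on use.
FEATURE_PRESETS: dict[tuple[str, str], list[str]] = {
    ("dt", "An"): ["RSI_664,434", "GI", "RSI_540,950", "NDI_1144,682,566"],
    ("dt", "TSS"): ["NDI_822,750,550", "RSI_664,434"],
    ("dt", "TA"): ["RSI_668,442", "RSI_540,950", "RSI_626,1018", "RSI_664,434"],
    ("dt", "TSS_TA"): ["NDVI", "NAI", "RSI_664,434", "NDI_822,750,552",
                       "RSI_540,950"],
    ("gbr", "An"): ["RSI_670,594", "NDI_1148,690,690", "RSI_592,650", "GI",
                    "RSI_638,614", "NDI_1144,684,562", "NDI_1148,688,688"],
    ("gbr", "TSS"): ["NDI_1126,696,694", "RSI_540,950", "NDI_1126,694,696",
                     "NDI_824,750,554", "NDI_822,750,550", "NDI_822,750,552",
                     "RSI_668,442", "RSI_610,628", "GI", "RSI_664,434"],
    ("gbr", "TA"): ["RSI_664,434", "RSI_626,1018", "RSI_668,442",
                    "NDI_822,750,550", "RSI_540,950", "NDI_1144,684,562"],
    ("gbr", "TSS_TA"): ["RSI_626,1018", "RSI_670,594", "R_822,750,552", "NAI",
                        "RSI_668,442", "RSI_664,434", "R_1144,684,562",
                        "RSI_680,1140"],
}


# ---------------------------------------------------------------------------
# reporting

@dataclass
class ModelReport:
    trait: str
    kind: ModelKind
    params: str
    feature_names: list[str]
    train_r2: float
    train_rmse: float
    cv_r2: float
    cv_rmse: float
    cv_pvalue: float
    oof_predictions: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.train_rmse < 0 or self.cv_rmse < 0:
            raise ValueError("RMSE must be non-negative")
        if self.train_r2 > 1 or self.cv_r2 > 1:
            raise ValueError("R² cannot exceed 1")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("trait", "kind", "params", "feature_names", "train_r2",
              "train_rmse", "cv_r2", "cv_rmse", "cv_pvalue")}
        d["oof_predictions"] = np.asarray(self.oof_predictions).tolist()
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def table_row(self) -> dict:
        """One row in the report-table shape."""
        return {
            "Variable": self.trait,
            "Proposed features": ", ".join(self.feature_names),
            "Optimal parameters": self.params,
            "Train R2": f"{self.train_r2:.2f}{significance_stars(self.cv_pvalue)}",
            "Train RMSE": round(self.train_rmse, 2),
            "CV R2": f"{self.cv_r2:.2f}{significance_stars(self.cv_pvalue)}",
            "CV RMSE": round(self.cv_rmse, 2),
        }


# ---------------------------------------------------------------------------
# model-style front end

class SRIRegression:
    """Trait ~ spectral-index regression with LOOCV model selection.

    Parameters
    ----------
    features : DataFrame of index values (samples x indices)
    target : per-sample trait values
    kind : "dt" or "gbr"
    trait : trait name, for reporting
    grid : optional hyperparameter grid override
    seed : random state threaded into every fitted model
    """

    def __init__(self, features: pd.DataFrame, target: np.ndarray,
                 kind: ModelKind = "gbr", trait: str = "y",
                 grid=None, seed: int = 0):
        if kind not in ("dt", "gbr"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.features = features
        self.target = np.asarray(target, dtype=float)
        self.kind = kind
        self.trait = trait
        self.seed = seed
        self.grid = list(grid) if grid is not None else default_grid(kind, seed=seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str,
                       feature_columns: list[str] | None = None,
                       **kw) -> "SRIRegression":
        cols = feature_columns or [c for c in df.columns if c != trait]
        return cls(df[cols], df[trait].to_numpy(dtype=float), trait=trait, **kw)

    def fit(self, features: str | list[str] = "all",
            max_subset: int = 10) -> "SRIRegressionResults":
        """Tune, optionally fuse features, and evaluate by LOOCV.

        ``features`` is ``"all"`` (use every column), ``"select"`` (greedy
        forward fusion up to ``max_subset``), or an explicit column list.
        """
        if features == "all":
            names = list(self.features.columns)
            spec, cv_rmse_val = tune_hyperparameters(self.features, self.target,
                                                     self.grid)
        elif features == "select":
            names, spec, cv_rmse_val = select_feature_subset(
                self.features, self.target, self.kind, max_subset,
                grid=self.grid, seed=self.seed)
        else:
            names = list(features)
            spec, cv_rmse_val = tune_hyperparameters(self.features[names],
                                                     self.target, self.grid)
        X = self.features[names]
        cv_r2, cv_rmse_val, oof = loocv_evaluate(X, self.target, spec)
        est = spec.build().fit(np.asarray(X, dtype=float), self.target)
        train_pred = est.predict(np.asarray(X, dtype=float))
        from scipy import stats as _st

        if np.ptp(oof) > 0:
            cv_p = float(_st.linregress(oof, self.target).pvalue)
        else:
            cv_p = 1.0
        report = ModelReport(
            trait=self.trait, kind=self.kind, params=spec.label(),
            feature_names=names,
            train_r2=r_squared(self.target, train_pred),
            train_rmse=rmse(self.target, train_pred),
            cv_r2=cv_r2, cv_rmse=cv_rmse_val, cv_pvalue=cv_p,
            oof_predictions=oof,
        )
        return SRIRegressionResults(self, spec, est, report)


class SRIRegressionResults:
    """Fitted-model container: estimates, CV diagnostics, summary table."""

    def __init__(self, model: SRIRegression, spec, estimator, report: ModelReport):
        self.model = model
        self.spec = spec
        self.estimator = estimator
        self.report = report

    @property
    def cv_r2(self) -> float:
        return self.report.cv_r2

    @property
    def cv_rmse(self) -> float:
        return self.report.cv_rmse

    @property
    def train_r2(self) -> float:
        return self.report.train_r2

    @property
    def train_rmse(self) -> float:
        return self.report.train_rmse

    @property
    def oof_predictions(self) -> np.ndarray:
        return self.report.oof_predictions

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([self.report.table_row()])

    def plot_observed_vs_predicted(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.target
        ax.scatter(y, self.oof_predictions, s=12)
        lim = [min(y.min(), self.oof_predictions.min()),
               max(y.max(), self.oof_predictions.max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"observed {self.report.trait}")
        ax.set_ylabel("LOOCV prediction")
        return ax
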