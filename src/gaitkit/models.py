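"""Estimation models: screening, stepwise selection, hierarchical regression.

The eleven inertial variables partition into four directional categories:

* lateral:   MAG-L, IMP-L, ANG-L
* vertical:  MAG-V, IMP-V
* anterior:  MAG-A, IMP-A, ANG-A
* inclusive: VM, VM10, ST

For each biomechanical target a subset of inertial variables is chosen by
forward stepwise selection (adjusted-R² criterion with k-fold
cross-validation across subjects), then entered into an ordinary
least-squares model in directional blocks: the target's primary axis first,
the remaining axes in cyclic order, and the non-directional (inclusive)
variables last.  Each block's entry reports the multiple correlation R, the
adjusted R², and ΔR² — the change in *adjusted* R² from the previous block,
which may be negative.  A block with no selected variables contributes a
step with ΔR² = 0 and otherwise unchanged statistics.

The public surface follows the statsmodels idiom: build a
:class:`BiomechEstimationModel` from a cohort summary table, call ``fit()``,
and read estimates, uncertainties and the step table off the returned
:class:`BiomechEstimationResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ModelError, ParameterError
from .trial_summary import flag_outlier_subjects

INERTIAL_VARS = [
    "vm",
    "vm10",
    "mag_l",
    "mag_v",
    "mag_a",
    "imp_l",
    "imp_v",
    "imp_a",
    "ang_l",
    "ang_a",
    "st",
]
BIOMECH_VARS = ["kfm", "kam", "agrf", "vgrf"]

#: Directional categories of the inertial variables.
CATEGORIES = {
    "lateral": ["mag_l", "imp_l", "ang_l"],
    "vertical": ["mag_v", "imp_v"],
    "anterior": ["mag_a", "imp_a", "ang_a"],
    "inclusive": ["vm", "vm10", "st"],
}

#: Primary direction of each biomechanical target.
PRIMARY_AXIS = {"kfm": "anterior", "kam": "lateral", "agrf": "anterior", "vgrf": "vertical"}

_AXIS_CYCLE = ["anterior", "vertical", "lateral"]


def direction_order(target: str) -> list[str]:
    """Block entry order for a target: primary axis first, then the other
    axes continuing around the anterior→vertical→lateral cycle, inclusive
    variables always last."""
    target = target.lower()
    if target not in PRIMARY_AXIS:
        raise ParameterError(f"unknown target {target!r}; expected one of {BIOMECH_VARS}")
    start = _AXIS_CYCLE.index(PRIMARY_AXIS[target])
    return [_AXIS_CYCLE[(start + i) % 3] for i in range(3)] + ["inclusive"]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1); requires n > p + 1."""
    if n <= p + 1:
        raise ModelError(f"adjusted R² undefined for n={n}, p={p} (need n > p + 1)")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# Pearson screening
# ---------------------------------------------------------------------------


@dataclass
class PearsonScreen:
    """Feature-by-target correlation table with significance annotation."""

    r: pd.DataFrame
    p: pd.DataFrame
    alphas: tuple = (0.05, 0.01)

    @property
    def formatted(self) -> pd.DataFrame:
        """r values with stars; entries that miss the loosest alpha are blank."""
        loose, strict = max(self.alphas), min(self.alphas)
        out = pd.DataFrame("-", index=self.r.index, columns=self.r.columns)
        for i in self.r.index:
            for c in self.r.columns:
                r, p = self.r.loc[i, c], self.p.loc[i, c]
                if np.isnan(r) or p >= loose:
                    continue
                stars = "**" if p < strict else "*"
                out.loc[i, c] = f"{r:.2f} {stars}"
        return out


def pearson_screen(X: pd.DataFrame, Y: pd.DataFrame, alphas=(0.05, 0.01)) -> PearsonScreen:
    """Pairwise Pearson correlations between features (X) and targets (Y).

    p-values use the exact t transform with n - 2 degrees of freedom.
    Zero-variance columns yield NaN entries.
    """
    if len(X) != len(Y):
        raise ParameterError("X and Y must have the same number of rows")
    n = len(X)
    if n < 3:
        raise ParameterError("need at least 3 observations for a correlation")
    r = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    p = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    for fx in X.columns:
        for fy in Y.columns:
            x = X[fx].to_numpy(dtype=float)
            y = Y[fy].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[fx, fy] = np.nan
                p.loc[fx, fy] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[fx, fy] = rr
            p.loc[fx, fy] = pp
    return PearsonScreen(r=r, p=p, alphas=tuple(alphas))


# ---------------------------------------------------------------------------
# Stepwise selection with k-fold cross-validation
# ---------------------------------------------------------------------------


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R² of an OLS fit with intercept, via least squares."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return 1.0 - np.sum(resid**2) / ss_tot


def _cv_scores(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]):
    """(mean training adjusted R², pooled out-of-fold R²) for one variable set."""
    n, p = len(y), X.shape[1] if X.ndim == 2 else 0
    train_adj = []
    oof_pred = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        if len(train) <= p + 1:
            return None
        A = np.column_stack([np.ones(len(train)), X[train]])
        beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        resid = y[train] - A @ beta
        ss_tot = np.sum((y[train] - y[train].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        train_adj.append(adjusted_r2(r2, len(train), p))
        At = np.column_stack([np.ones(len(fold)), X[fold]])
        oof_pred[fold] = At @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    oof_r2 = 1.0 - np.sum((y - oof_pred) ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(np.mean(train_adj)), float(oof_r2)


@dataclass
class StepwiseSelection:
    """Outcome of forward selection: the chosen set and the decision log."""

    selected: list[str]
    log: pd.DataFrame
    k_folds: int
    seed: int


def stepwise_select(
    X: pd.DataFrame,
    y,
    k_folds: int = 10,
    seed: int = 0,
    cv: bool = True,
    p_enter: float = 0.05,
) -> StepwiseSelection:
    """Forward stepwise selection of regressors for one target.

    At each round the candidate maximising the cross-validated criterion
    (mean across folds of the training-fit adjusted R²) is proposed; it is
    accepted when (a) that criterion increases, (b) the full-sample adjusted
    R² increases, (c) its partial t-test is significant at ``p_enter``, and,
    with ``cv=True``, (d) the pooled out-of-fold prediction R² increases.
    Ties break toward the lower column index.  Fold assignment partitions
    subjects deterministically given ``seed``.  With ``cv=False`` the
    selection reduces to the classic adjusted-R²/p-to-enter forward pass.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k_folds < 2:
        raise ParameterError("k_folds must be at least 2")
    if n < k_folds:
        raise ParameterError(f"need at least k_folds={k_folds} subjects, got {n}")
    if np.std(y) == 0:
        warnings.warn("constant target; no variables selected", stacklevel=2)
        return StepwiseSelection([], pd.DataFrame(), k_folds, seed)

    folds = _kfold_indices(n, k_folds, seed)
    cols = list(X.columns)
    Xmat = X.to_numpy(dtype=float)

    selected: list[str] = []
    current_cv = 0.0
    base = _cv_scores(np.empty((n, 0)), y, folds)
    current_oof = base[1]
    current_adj = 0.0
    log_rows = []

    while True:
        remaining = [c for c in cols if c not in selected]
        if not remaining or n <= len(selected) + 2:
            break
        best = None
        for c in remaining:
            idx = [cols.index(v) for v in selected + [c]]
            scores = _cv_scores(Xmat[:, idx], y, folds)
            if scores is None:
                continue
            if best is None or scores[0] > best[1] + 1e-12:
                best = (c, scores[0], scores[1])
        if best is None:
            break
        cand, cand_cv, cand_oof = best
        idx = [cols.index(v) for v in selected + [cand]]
        full_r2 = _ols_r2(Xmat[:, idx], y)
        full_adj = adjusted_r2(full_r2, n, len(idx))
        ols = sm.OLS(y, sm.add_constant(Xmat[:, idx])).fit()
        p_val = float(ols.pvalues[-1])

        accept = (
            cand_cv > current_cv
            and full_adj > current_adj
            and p_val < p_enter
            and (not cv or cand_oof > current_oof)
        )
        log_rows.append(
            {
                "variable": cand,
                "cv_train_adj_r2": cand_cv,
                "oof_r2": cand_oof,
                "full_adj_r2": full_adj,
                "p_value": p_val,
                "accepted": accept,
            }
        )
        if not accept:
            break
        selected.append(cand)
        current_cv, current_oof, current_adj = cand_cv, cand_oof, full_adj

    return StepwiseSelection(selected, pd.DataFrame(log_rows), k_folds, seed)


def group_by_category(selected: list[str]) -> dict[str, list[str]]:
    """Partition a selected variable list by directional category,
    preserving selection order within each category."""
    out = {cat: [v for v in selected if v in members] for cat, members in CATEGORIES.items()}
    unknown = [v for v in selected if not any(v in m for m in CATEGORIES.values())]
    if unknown:
        raise ParameterError(f"variables without a directional category: {unknown}")
    return out


# ---------------------------------------------------------------------------
# Hierarchical regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionReport:
    """Stepwise block-entry statistics for one target.

    ``steps`` has one row per category in entry order with columns
    ``category, variables, n_vars, R, r2, adj_r2, delta_r2`` where
    ``delta_r2`` is the change in adjusted R² from the previous step.
    """

    target: str
    mode: str
    order: list[str]
    selected: dict[str, list[str]]
    steps: pd.DataFrame
    n_subjects: int


def hierarchical_regression(
    X: pd.DataFrame,
    y,
    selected_by_category: dict[str, list[str]],
    order: list[str],
) -> RegressionReport:
    """Cumulative OLS fits entered category-block by category-block.

    Empty categories contribute a step with ΔR² = 0 and carried-forward
    statistics (R = 0 when nothing has entered yet).  Raises
    :class:`ModelError` on a singular design, naming the offending block.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    total = sum(len(v) for v in selected_by_category.values())
    if total and n <= total + 1:
        raise ModelError(f"too few subjects (n={n}) for {total} predictors")

    cum: list[str] = []
    prev_r, prev_r2, prev_adj = 0.0, 0.0, 0.0
    rows = []
    for cat in order:
        members = selected_by_category.get(cat, [])
        if not members:
            rows.append(
                {
                    "category": cat,
                    "variables": "",
                    "n_vars": 0,
                    "R": prev_r,
                    "r2": prev_r2,
                    "adj_r2": prev_adj,
                    "delta_r2": 0.0,
                }
            )
            continue
        cum = cum + list(members)
        A = np.column_stack([np.ones(n), X[cum].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise ModelError(f"singular design at the {cat!r} step (variables {cum})")
        r2 = _ols_r2(X[cum].to_numpy(dtype=float), y)
        adj = adjusted_r2(r2, n, len(cum))
        rows.append(
            {
                "category": cat,
                "variables": ",".join(members),
                "n_vars": len(members),
                "R": float(np.sqrt(max(r2, 0.0))),
                "r2": r2,
                "adj_r2": adj,
                "delta_r2": adj - prev_adj,
            }
        )
        prev_r, prev_r2, prev_adj = float(np.sqrt(max(r2, 0.0))), r2, adj
    return RegressionReport(
        target="",
        mode="",
        order=list(order),
        selected=selected_by_category,
        steps=pd.DataFrame(rows),
        n_subjects=n,
    )


# ---------------------------------------------------------------------------
# statsmodels-style Model / Results
# ---------------------------------------------------------------------------


class BiomechEstimationModel:
    """Estimate one biomechanical gait variable from the inertial variables.

    Parameters
    ----------
    endog : array-like
        Per-subject target values (trial average or Symmetry Index).
    exog : DataFrame
        Per-subject inertial variables, columns named as in
        :data:`INERTIAL_VARS`.
    target : str
        One of ``kfm``, ``kam``, ``agrf``, ``vgrf`` — fixes the block order.
    mode : str
        ``'average'`` or ``'symmetry'`` (metadata, echoed into results).

    Examples
    --------
    >>> model = BiomechEstimationModel.from_summary_table(summary, "agrf")
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, endog, exog: pd.DataFrame, target: str, mode: str = "average"):
        self.target = target.lower()
        if self.target not in BIOMECH_VARS:
            raise ParameterError(f"unknown target {target!r}")
        if mode not in ("average", "symmetry"):
            raise ParameterError("mode must be 'average' or 'symmetry'")
        missing = [v for v in INERTIAL_VARS if v not in exog.columns]
        if missing:
            raise ParameterError(f"exog is missing inertial variables: {missing}")
        self.mode = mode
        self.exog = exog[INERTIAL_VARS].reset_index(drop=True).astype(float)
        self.endog = pd.Series(np.asarray(endog, dtype=float), name=self.target)
        if len(self.endog) != len(self.exog):
            raise ParameterError("endog and exog lengths differ")
        if self.exog.isna().any().any() or self.endog.isna().any():
            raise ParameterError("missing values are not supported")

    @classmethod
    def from_summary_table(
        cls, summary: pd.DataFrame, target: str, mode: str = "average"
    ) -> "BiomechEstimationModel":
        """Build from a cohort summary table with avg_*/si_* columns."""
        prefix = "avg_" if mode == "average" else "si_"
        cols = {f"{prefix}{v}": v for v in INERTIAL_VARS}
        missing = [c for c in cols if c not in summary.columns]
        if missing:
            raise ParameterError(f"summary table is missing columns: {missing}")
        ycol = f"{prefix}{target.lower()}"
        if ycol not in summary.columns:
            raise ParameterError(f"summary table is missing target column {ycol}")
        exog = summary[list(cols)].rename(columns=cols)
        return cls(summary[ycol], exog, target, mode)

    def fit(
        self,
        k_folds: int = 10,
        seed: int = 0,
        cv: bool = True,
        p_enter: float = 0.05,
        stepwise: bool = True,
    ) -> "BiomechEstimationResults":
        """Run stepwise selection then the directional hierarchical regression."""
        if stepwise:
            selection = stepwise_select(
                self.exog, self.endog, k_folds=k_folds, seed=seed, cv=cv, p_enter=p_enter
            )
            selected = selection.selected
        else:
            selection = StepwiseSelection(list(INERTIAL_VARS), pd.DataFrame(), k_folds, seed)
            selected = list(INERTIAL_VARS)
        by_cat = group_by_category(selected)
        order = direction_order(self.target)
        report = hierarchical_regression(self.exog, self.endog, by_cat, order)
        report.target = self.target
        report.mode = self.mode

        if selected:
            final = sm.OLS(
                np.asarray(self.endog), sm.add_constant(self.exog[selected])
            ).fit()
        else:
            final = sm.OLS(
                np.asarray(self.endog), np.ones((len(self.endog), 1))
            ).fit()
        return BiomechEstimationResults(self, selection, report, final)


class BiomechEstimationResults:
    """Fitted estimation model: step table, estimates and uncertainties."""

    def __init__(self, model, selection, report, ols_results):
        self.model = model
        self.target = model.target
        self.mode = model.mode
        self.selection = selection
        self.selected = list(selection.selected)
        self.selected_by_category = report.selected
        self.report = report
        self.steps = report.steps
        self.ols_results = ols_results
        self.params = ols_results.params
        self.bse = ols_results.bse
        self.pvalues = ols_results.pvalues
        self.rsquared = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    @property
    def rsquared_adj(self) -> float:
        p = len(self.selected)
        return adjusted_r2(self.rsquared, self.nobs, p) if p else 0.0

    def summary(self) -> str:
        """Human-readable report mirroring the step-table layout."""
        lines = [
            f"Hierarchical estimation of {self.target.upper()} ({self.mode})",
            f"n = {self.nobs} subjects; selected: "
            + (", ".join(self.selected) if self.selected else "(none)"),
            "",
            f"{'Step':<10}{'Variables':<22}{'R':>7}{'Adj. R2':>9}{'dR2':>8}",
        ]
        for _, row in self.steps.iterrows():
            lines.append(
                f"{row['category']:<10}{row['variables']:<22}"
                f"{row['R']:>7.3f}{row['adj_r2']:>9.3f}{row['delta_r2']:>8.3f}"
            )
        lines.append("")
        lines.append(f"{'term':<12}{'coef':>10}{'se':>10}{'p':>9}")
        names = ["const"] + self.selected
        for name, b, se, p in zip(names, self.params, self.bse, self.pvalues):
            lines.append(f"{name:<12}{b:>10.4f}{se:>10.4f}{p:>9.4f}")
        return "\n".join(lines)

    def plot_delta_r2(self, ax=None):
        """Bar chart of the per-category adjusted-R² increments."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.bar(self.steps["category"], self.steps["delta_r2"])
        ax.set_ylabel("Δ adjusted R²")
        ax.set_title(f"{self.target.upper()} ({self.mode})")
        return ax


# ---------------------------------------------------------------------------
# Full model suite
# ---------------------------------------------------------------------------


@dataclass
class ModelSuiteResult:
    """Results for all four targets, with and without MAD-flagged subjects."""

    mode: str
    all_subjects: dict
    excluding_outliers: Optional[dict]
    outlier_ids: list
    correlations: PearsonScreen


def run_model_suite(
    summary: pd.DataFrame,
    mode: str = "average",
    seed: int = 0,
    k_folds: int = 10,
    cv: bool = True,
    p_enter: float = 0.05,
    mad_cutoff: float = 3.0,
) -> ModelSuiteResult:
    """Fit all four target models on a cohort summary table.

    Emits one fitted model per target both for the full cohort and with
    MAD-flagged subjects removed (the removal branch is skipped when nothing
    is flagged).
    """
    prefix = "avg_" if mode == "average" else "si_"
    flags = flag_outlier_subjects(summary, cutoff=mad_cutoff)
    outlier_ids = list(summary.loc[np.asarray(flags, bool), "subject_id"]) if "subject_id" in summary else list(summary.index[np.asarray(flags, bool)])

    X = summary[[f"{prefix}{v}" for v in INERTIAL_VARS]].rename(
        columns={f"{prefix}{v}": v for v in INERTIAL_VARS}
    )
    Y = summary[[f"{prefix}{v}" for v in BIOMECH_VARS]].rename(
        columns={f"{prefix}{v}": v for v in BIOMECH_VARS}
    )
    screen = pearson_screen(X, Y)

    def _fit_all(tbl: pd.DataFrame) -> dict:
        if len(tbl) < 8:
            raise ModelError(f"need at least 8 subjects, got {len(tbl)}")
        out = {}
        for tgt in BIOMECH_VARS:
            model = BiomechEstimationModel.from_summary_table(tbl, tgt, mode)
            out[tgt] = model.fit(k_folds=min(k_folds, len(tbl)), seed=seed, cv=cv, p_enter=p_enter)
        return out

    all_res = _fit_all(summary)
    excl_res = None
    if any(flags):
        excl_res = _fit_all(summary.loc[~np.asarray(flags, bool)].reset_index(drop=True))
    return ModelSuiteResult(
        mode=mode,
        all_subjects=all_res,
        excluding_outliers=excl_res,
        outlier_ids=outlier_ids,
        correlations=screen,
    )
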