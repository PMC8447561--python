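"""Univariate comparisons, correlation matrices, outcome tabulation,
LASSO-selected logistic prediction, and ROC/AUC comparison.

Conventions follow common clinical-biostatistics practice: continuous
variables are compared by Wilcoxon rank-sum (exact for small tie-free arms,
normal approximation with tie correction otherwise), categorical variables by
Pearson chi-square with Fisher's exact test when any observed 2x2 cell is
below 5, multiplicity by Bonferroni (0.05/m), and discrimination by the
Mann–Whitney AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ComparisonResult", "CorrelationMatrix", "OutcomeTable", "LassoFit",
    "RocResult", "group_compare", "spearman_matrix", "cluster_outcome_table",
    "lasso_select", "roc_auc", "compare_signature_auc", "LassoOutcomeModel",
    "continuous_cluster_score",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    variable: str
    test: str                      # wilcoxon_rank_sum | chi_square | fisher_exact
    statistic: float
    p_value: float
    group_summaries: dict[str, str]
    family_size: int
    threshold: float               # 0.05 / family_size exactly
    significant: bool
    note: str = ""


def _is_categorical(series: pd.Series, max_levels: int = 5) -> bool:
    vals = series.dropna().unique()
    return len(vals) <= max_levels and np.allclose(vals, np.round(vals))


def _wilcoxon(a: np.ndarray, b: np.ndarray):
    """Two-sided rank-sum p: exact when both arms <= 25 and tie-free."""
    combined = np.concatenate([a, b])
    if len(np.unique(combined)) == len(combined) and len(a) <= 25 and len(b) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_compare(table: pd.DataFrame, group_var: str,
                  variables: Sequence[str], family_size: int,
                  fisher_on_expected: bool = False) -> list[ComparisonResult]:
    """Per-variable unadjusted comparison across the levels of ``group_var``.

    Continuous → Wilcoxon rank-sum (two groups); categorical → chi-square,
    or Fisher's exact for 2x2 tables with any observed cell < 5 (set
    ``fisher_on_expected`` to trigger on expected counts instead).  Missing
    values are dropped per variable.  The Bonferroni family size attaches the
    0.05/m threshold to every result.
    """
    groups = table[group_var].dropna().unique()
    if len(groups) < 2:
        raise StatsError(f"{group_var!r} has < 2 levels")
    threshold = 0.05 / family_size
    results = []
    for var in variables:
        sub = table[[var, group_var]].dropna()
        note = ""
        if sub[var].nunique() <= 1:
            warnings.warn(f"{var}: single distinct value, degenerate test")
            results.append(ComparisonResult(
                variable=var, test="degenerate", statistic=0.0, p_value=1.0,
                group_summaries={}, family_size=family_size,
                threshold=threshold, significant=False,
                note="single distinct value"))
            continue
        if _is_categorical(sub[var]):
            ct = pd.crosstab(sub[var], sub[group_var])
            observed = ct.to_numpy()
            expected = sps.contingency.expected_freq(observed)
            trigger = (expected if fisher_on_expected else observed).min() < 5
            if trigger and observed.shape == (2, 2):
                stat, p = sps.fisher_exact(observed)
                test = "fisher_exact"
            else:
                if trigger:
                    note = "small cells but table larger than 2x2; chi-square used"
                stat, p, _, _ = sps.chi2_contingency(observed, correction=False)
                test = "chi_square"
            summaries = {
                str(g): ", ".join(
                    f"{lvl}: {int(c)} ({100 * c / ct[g].sum():.0f}%)"
                    for lvl, c in ct[g].items())
                for g in ct.columns
            }
        else:
            if len(groups) != 2:
                raise StatsError(
                    f"{var}: rank-sum comparison needs exactly 2 groups")
            a = sub.loc[sub[group_var] == groups[0], var].to_numpy(float)
            b = sub.loc[sub[group_var] == groups[1], var].to_numpy(float)
            stat, p = _wilcoxon(a, b)
            test = "wilcoxon_rank_sum"
            summaries = {}
            for g, arr in ((groups[0], a), (groups[1], b)):
                q1, med, q3 = np.percentile(arr, [25, 50, 75])
                summaries[str(g)] = f"{med:g} ({q1:g}, {q3:g})"
        results.append(ComparisonResult(
            variable=var, test=test, statistic=float(stat), p_value=float(p),
            group_summaries=summaries, family_size=family_size,
            threshold=threshold, significant=bool(p < threshold), note=note))
    return results


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p_values: pd.DataFrame
    n_obs: pd.DataFrame
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)


def spearman_matrix(table: pd.DataFrame, row_features: Sequence[str],
                    col_features: Sequence[str],
                    min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman ρ between two feature sets.

    Ties use average ranks; p-values come from the t approximation.  Pairs
    with fewer than ``min_n`` complete observations are left NaN with a
    recorded reason.
    """
    rho = pd.DataFrame(index=list(row_features), columns=list(col_features),
                       dtype=float)
    pv = rho.copy()
    nn = rho.copy()
    reasons = {}
    for r in row_features:
        for c in col_features:
            sub = pd.concat([table[r], table[c]], axis=1,
                            keys=["_r", "_c"]).dropna()
            nn.loc[r, c] = len(sub)
            if len(sub) < min_n:
                reasons[(r, c)] = f"only {len(sub)} complete observations"
                continue
            res = sps.spearmanr(sub["_r"], sub["_c"])
            rho.loc[r, c] = float(res.statistic)
            pv.loc[r, c] = float(res.pvalue)
    return CorrelationMatrix(rho=rho, p_values=pv, n_obs=nn, reasons=reasons)


# ---------------------------------------------------------------------------
# cluster-outcome tabulation
# ---------------------------------------------------------------------------

@dataclass
class OutcomeTable:
    """Counts and percentages of outcomes per cluster (percentages computed
    as 100*count/cluster_n, rounded to one decimal)."""

    counts: pd.DataFrame           # clusters x outcomes (+ mortality_28d)
    percentages: pd.DataFrame
    denominators: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.astype(str) + " (" + \
            self.percentages.map(lambda v: f"{v:.1f}") + ")"
        return out


OUTCOME_ORDER = ("rapid_recovery", "cci", "early_death")


def cluster_outcome_table(cluster_labels: pd.Series, outcomes: pd.Series,
                          mortality_28d: Optional[pd.Series] = None) -> OutcomeTable:
    """Per-cluster outcome counts/percentages (and 28-day mortality)."""
    idx = cluster_labels.index
    missing = outcomes.reindex(idx).isna()
    if missing.any():
        raise StatsError(
            f"clustered patients without adjudicated outcome: "
            f"{list(idx[missing])}")
    clusters = sorted(cluster_labels.unique())
    if any((cluster_labels == c).sum() == 0 for c in clusters) or not clusters:
        raise StatsError("empty cluster")
    rows_c, rows_p, denoms = [], [], {}
    cols = list(OUTCOME_ORDER) + (["mortality_28d"] if mortality_28d is not None else [])
    for c in clusters:
        members = idx[cluster_labels == c]
        n = len(members)
        denoms[str(c)] = n
        counts = {o: int((outcomes.loc[members] == o).sum()) for o in OUTCOME_ORDER}
        if mortality_28d is not None:
            counts["mortality_28d"] = int(mortality_28d.loc[members].astype(bool).sum())
        rows_c.append([counts[col] for col in cols])
        rows_p.append([round(100.0 * counts[col] / n, 1) for col in cols])
    return OutcomeTable(
        counts=pd.DataFrame(rows_c, index=[str(c) for c in clusters], columns=cols),
        percentages=pd.DataFrame(rows_p, index=[str(c) for c in clusters], columns=cols),
        denominators=denoms,
    )


# ---------------------------------------------------------------------------
# LASSO-selected logistic prediction
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    candidates: list[str]
    log_transformed: list[str]
    lambda_grid: np.ndarray
    lambda_selected: float
    cv_deviance: np.ndarray
    selected: list[str]
    path: pd.DataFrame                      # lambda, df, deviance, coefficients
    odds_ratios: pd.DataFrame               # OR, CI low/high, p per selected var
    n_events: int
    n_used: int
    warnings: list[str] = field(default_factory=list)


class LassoOutcomeModel(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic selection with an unpenalized refit.

    The design is standardized (mean 0, SD 1); listed features are
    log-transformed first (ApoA-I by convention).  λ runs over a geometric
    grid from λ_max (first entry) downward; the value minimizing k-fold
    cross-validated deviance (binomial, seeded folds) is selected, nonzero
    coefficients form the selected set, and a plain logistic refit on the
    selected variables yields odds ratios with 95% Wald confidence intervals.
    """

    def __init__(self, candidates: Optional[Sequence[str]] = None,
                 log_features: Sequence[str] = ("apoa1",),
                 n_lambdas: int = 30, lambda_min_ratio: float = 1e-3,
                 cv_folds: int = 10, seed: int = 0):
        self.candidates = candidates
        self.log_features = log_features
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds
        self.seed = seed

    # -- helpers ------------------------------------------------------------
    def _design(self, X: pd.DataFrame):
        cand = list(self.candidates) if self.candidates is not None \
            else list(X.columns)
        D = X[cand].astype(float).copy()
        for f in self.log_features:
            if f in D.columns:
                if (D[f] <= 0).any():
                    raise StatsError(f"{f}: log transform needs positive values")
                D[f] = np.log(D[f])
        return cand, D

    @staticmethod
    def _fit_l1(Z: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
        # sklearn's C is the inverse of the total penalty; our λ is per-sample
        C = 1.0 / (lam * len(y)) if lam > 0 else 1e12
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-8)
        clf.fit(Z, y)
        return clf.coef_.ravel()

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "LassoOutcomeModel":
        cand, D = self._design(X)
        mask = D.notna().all(axis=1) & pd.Series(y, index=D.index).notna()
        D = D.loc[mask]
        yv = np.asarray(pd.Series(y).loc[mask], dtype=int)
        if len(np.unique(yv)) < 2:
            raise StatsError("outcome has a single class after complete-case filter")
        notes = []
        n_events = int(yv.sum())
        if min(n_events, len(yv) - n_events) < 10:
            notes.append(f"only {n_events} events: estimates may be unstable")
            warnings.warn(notes[-1])

        mu = D.mean()
        sd = D.std(ddof=1).replace(0.0, 1.0)
        Z = ((D - mu) / sd).to_numpy()

        # λ_max: smallest penalty with an all-zero solution (KKT bound)
        p_bar = yv.mean()
        lam_max = np.abs(Z.T @ (yv - p_bar)).max() / len(yv)
        grid = lam_max * np.logspace(
            0, np.log10(self.lambda_min_ratio), self.n_lambdas)

        folds = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                                random_state=self.seed)
        deviance = np.zeros(len(grid))
        for train, test in folds.split(Z, yv):
            for gi, lam in enumerate(grid):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / (lam * len(train)),
                    solver="liblinear", max_iter=2000, tol=1e-8)
                clf.fit(Z[train], yv[train])
                p = np.clip(clf.predict_proba(Z[test])[:, 1], 1e-12, 1 - 1e-12)
                deviance[gi] += -2.0 * np.sum(
                    yv[test] * np.log(p) + (1 - yv[test]) * np.log(1 - p))
        best = int(np.argmin(deviance))
        lam_star = float(grid[best])

        path_rows = []
        for lam in grid:
            coef = self._fit_l1(Z, yv, lam)
            path_rows.append({"lambda": lam, "df": int((coef != 0).sum()),
                              **{c: coef[i] for i, c in enumerate(cand)}})
        path = pd.DataFrame(path_rows)
        coef_star = self._fit_l1(Z, yv, lam_star)
        selected = [c for c, b in zip(cand, coef_star) if b != 0.0]

        odds = self._refit(D, yv, selected, notes)
        self.fit_ = LassoFit(
            candidates=cand,
            log_transformed=[f for f in self.log_features if f in cand],
            lambda_grid=grid, lambda_selected=lam_star, cv_deviance=deviance,
            selected=selected, path=path, odds_ratios=odds,
            n_events=n_events, n_used=len(yv), warnings=notes,
        )
        self._mu, self._sd, self._cand = mu, sd, cand
        self.classes_ = np.array([0, 1])
        return self

    def _refit(self, D: pd.DataFrame, yv: np.ndarray, selected: list[str],
               notes: list[str]) -> pd.DataFrame:
        import statsmodels.api as sm

        if not selected:
            return pd.DataFrame(
                columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"])
        Xs = sm.add_constant(D[selected].to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, Xs).fit(disp=0, maxiter=200)
            params = res.params[1:]
            ci = res.conf_int()[1:]
            pvals = res.pvalues[1:]
            if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 30:
                notes.append("possible separation in refit: CIs unstable")
        except Exception as exc:           # separation can break the refit
            notes.append(f"refit failed ({exc}); odds ratios unavailable")
            return pd.DataFrame(
                columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"])
        self.refit_result_ = res
        return pd.DataFrame({
            "variable": selected,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p_value": pvals,
        })

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not self.fit_.selected:
            p = np.full(len(X), self.fit_.n_events / self.fit_.n_used)
            return np.column_stack([1 - p, p])
        _, D = self._design(X)
        eta = self.refit_result_.predict(
            np.column_stack([np.ones(len(D)), D[self.fit_.selected].to_numpy()]))
        return np.column_stack([1 - eta, eta])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def lasso_select(table: pd.DataFrame, candidates: Sequence[str],
                 outcome: pd.Series, cv_folds: int = 10, seed: int = 0,
                 log_features: Sequence[str] = ("apoa1",),
                 n_lambdas: int = 30) -> LassoFit:
    """Functional wrapper: returns the :class:`LassoFit` record."""
    model = LassoOutcomeModel(
        candidates=candidates, log_features=log_features, cv_folds=cv_folds,
        seed=seed, n_lambdas=n_lambdas)
    model.fit(table, outcome)
    return model.fit_


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    predictor: str
    auc: float
    points: pd.DataFrame           # fpr, tpr
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], outcome: Sequence[int],
            predictor: str = "score") -> RocResult:
    """AUC by the rank-based Mann–Whitney estimator (ties count 1/2) with a
    threshold-sweep ROC curve; supports binary predictors (2-point ROC)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("both outcome classes must be present")
    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) \
        / (len(pos) * len(neg))
    thresholds = np.unique(s)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pred = s >= t
        pts.append((float((pred & (y == 0)).sum() / len(neg)),
                    float((pred & (y == 1)).sum() / len(pos))))
    points = pd.DataFrame(pts, columns=["fpr", "tpr"])
    return RocResult(predictor=predictor, auc=float(auc), points=points,
                     n_pos=len(pos), n_neg=len(neg))


def continuous_cluster_score(z_matrix: pd.DataFrame, semantic: pd.Series) -> pd.Series:
    """Signed projection onto the hypo–normo centroid axis in z-space.

    Higher = closer to the Hypolipoprotein centroid; an optional continuous
    alternative to binary cluster membership as a ROC predictor.
    """
    from .cluster import HYPO, NORMO

    hypo_c = z_matrix.loc[semantic[semantic == HYPO].index].mean()
    normo_c = z_matrix.loc[semantic[semantic == NORMO].index].mean()
    axis = (hypo_c - normo_c).to_numpy()
    axis = axis / np.linalg.norm(axis)
    mid = (hypo_c + normo_c).to_numpy() / 2.0
    return pd.Series((z_matrix.to_numpy() - mid) @ axis, index=z_matrix.index,
                     name="cluster_score")


def compare_signature_auc(cluster_membership: pd.Series, sofa: pd.Series,
                          apache: pd.Series, outcome: pd.Series) -> list[RocResult]:
    """AUCs of binary cluster membership (hypo=1) vs total SOFA vs APACHE II
    for predicting rapid recovery (0) vs CCI/early death (1), side by side."""
    idx = cluster_membership.index
    y = outcome.loc[idx].astype(int)
    return [
        roc_auc(cluster_membership.loc[idx].astype(float), y, "cluster"),
        roc_auc(sofa.loc[idx].astype(float), y, "sofa"),
        roc_auc(apache.loc[idx].astype(float), y, "apache2"),
    ]
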