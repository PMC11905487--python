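"""Inference layer: Spearman + bootstrap + FDR, standardized regression,
and all-relevant feature selection with shadow features (Boruta) under a
five-seed consensus.

The correlation surface mirrors the study design: Spearman's rho between
autonomic measures (log LF, log HF, EDR, smoking) and gating measures
(S1, S2 amplitudes, S2/S1 ratio), with percentile confidence intervals
from 1000 paired bootstrap resamples and Benjamini-Hochberg control of the
false discovery rate across the family. Predictors surviving the screen
enter a standardized ordinary-least-squares regression of the gating
ratio. The EEG-to-autonomic link is explored with Boruta: every feature is
shadowed by a shuffled copy, a random forest is fitted, and a feature
scores a "hit" whenever its importance exceeds the best shadow's; repeated
binomial testing of hit counts confirms or rejects features, and only
features confirmed under every one of five random seeds are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "spearman",
    "bootstrap_ci",
    "fdr_bh",
    "standardized_regression",
    "boruta",
    "boruta_consensus",
    "correlation_report",
    "BorutaResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray) -> np.ndarray:
    return sstats.rankdata(a, method="average")


def spearman(x: np.ndarray, y: np.ndarray, method: str = "t") -> tuple[float, float]:
    """Spearman's rho with a two-sided p-value.

    rho is the Pearson correlation of midranks (average ranks for ties).
    ``method="t"`` uses the t-approximation with n-2 degrees of freedom;
    ``method="exact"`` uses the exact permutation null (sensible for
    n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined: a variable has zero variance")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        res = sstats.spearmanr(x, y, alternative="two-sided")
        return rho, float(res.pvalue) if n > 10 else _exact_spearman_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Exact permutation p-value by full enumeration (tiny n only)."""
    from itertools import permutations

    n = rx.size
    count = total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for Spearman's rho.

    Pairs are resampled with replacement ``n_boot`` times; degenerate
    resamples (zero variance in either variable) are skipped with a log
    entry. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 pairs for a bootstrap interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    rx = sstats.rankdata(xs, method="average", axis=1)
    ry = sstats.rankdata(ys, method="average", axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    ok = denom > 0
    if not ok.all():
        logger.info("skipped %d degenerate bootstrap resamples", int((~ok).sum()))
    rhos = (rx[ok] * ry[ok]).sum(axis=1) / denom[ok]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rhos, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept.

    ``adjusted_i = min_{j >= rank(i)} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def correlation_report(
    table: pd.DataFrame,
    predictors: list[str],
    outcomes: list[str],
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spearman rho, bootstrap CI, raw and FDR-adjusted p per pair.

    One row per (predictor, outcome) pair; the FDR correction spans the
    whole family of pairs.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    children = ss.spawn(len(predictors) * len(outcomes))
    k = 0
    for pred in predictors:
        for out in outcomes:
            x = table[pred].to_numpy(dtype=float)
            y = table[out].to_numpy(dtype=float)
            rho, p = spearman(x, y)
            lo, hi = bootstrap_ci(
                x, y, n_boot=n_boot, level=level,
                seed=int(children[k].generate_state(1)[0] % (2**31)),
            )
            rows.append({"predictor": pred, "outcome": out, "rho": rho,
                         "ci_low": lo, "ci_high": hi, "p_raw": p})
            k += 1
    rep = pd.DataFrame(rows)
    rep["p_fdr"] = fdr_bh(rep["p_raw"].to_numpy())
    return rep


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def standardized_regression(X: pd.DataFrame, y: np.ndarray | pd.Series) -> pd.DataFrame:
    """Standardized (beta) coefficients from ordinary least squares.

    Predictors and outcome are z-scored (ddof=1) before the fit, so the
    coefficients are standardized betas; p-values are two-sided t-tests.
    Raises on rank-deficient design matrices, naming the collinear columns.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    sds = X.std(ddof=1)
    const_cols = list(sds.index[sds == 0])
    if const_cols:
        raise ValueError(f"constant predictor column(s): {const_cols}")
    Z = (X - X.mean()) / sds
    if np.linalg.matrix_rank(Z.to_numpy()) < k:
        corr = Z.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    if np.std(y, ddof=1) == 0:
        raise ValueError("outcome has zero variance")
    zy = (y - y.mean()) / np.std(y, ddof=1)
    fit = sm.OLS(zy, sm.add_constant(Z)).fit()
    return pd.DataFrame(
        {"beta": fit.params.drop("const"), "p": fit.pvalues.drop("const")}
    )


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    """Per-feature decisions of one Boruta run."""

    decisions: pd.DataFrame  # index=features: status, hits, n_iter, imp mean/sd
    n_iter: int
    seed: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions["status"] == "confirmed"])


def boruta(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    seed: int = 0,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_estimators: int = 500,
    max_features: str | float = "sqrt",
    importance: str = "impurity",
    mc_adjust: bool = True,
) -> BorutaResult:
    """All-relevant feature selection with shadow features.

    Each iteration appends one shuffled (shadow) copy of every still-active
    feature, fits a random-forest regressor, and credits a real feature
    with a hit when its importance exceeds the best shadow importance. A
    two-sided binomial test of the hit count against chance (p = 0.5) at
    ``alpha`` confirms (significantly many hits) or rejects (significantly
    few) the feature; with ``mc_adjust`` (default, and required for a
    controlled false-confirmation rate over many features) the binomial
    p-values are Bonferroni-corrected across the feature count before the
    decision. Rejected features leave the model. Features still
    undecided after ``max_iter`` iterations are labelled tentative and
    treated as not important downstream. Deterministic given ``seed``.

    ``importance`` selects the forest's impurity-based importances
    (default; fast) or out-of-model permutation importances
    (``"permutation"``; markedly slower).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.any(~np.isfinite(y)):
        raise ValueError("missing values are not supported; complete the dataset first")
    if len(X) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")

    rng = np.random.default_rng(seed)
    feats = list(X.columns)
    p = len(feats)
    status = {f: "tentative" for f in feats}
    hits = dict.fromkeys(feats, 0)
    tested = dict.fromkeys(feats, 0)
    imp_hist: dict[str, list[float]] = {f: [] for f in feats}
    in_model = list(feats)      # confirmed features stay in the forest
    undecided = set(feats)

    it = 0
    Xv = X.to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(feats)}
    while undecided and it < max_iter:
        it += 1
        cols = [col_of[f] for f in in_model]
        Xa = Xv[:, cols]
        shadows = rng.permuted(Xa, axis=0)
        Z = np.hstack([Xa, shadows])
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(Z, y)
        if importance == "permutation":
            from sklearn.inspection import permutation_importance

            imp = permutation_importance(
                rf, Z, y, n_repeats=3,
                random_state=int(rng.integers(2**31)),
            ).importances_mean
        else:
            imp = rf.feature_importances_
        real_imp = imp[: len(in_model)]
        shadow_max = imp[len(in_model):].max()
        for f, v in zip(in_model, real_imp):
            imp_hist[f].append(float(v))
            if f in undecided:
                tested[f] += 1
                if v > shadow_max:
                    hits[f] += 1
        for f in list(undecided):
            pv = sstats.binomtest(hits[f], tested[f], 0.5).pvalue
            if mc_adjust:
                pv = min(1.0, pv * p)
            if pv < alpha:
                if hits[f] > tested[f] / 2:
                    status[f] = "confirmed"
                else:
                    status[f] = "rejected"
                    in_model.remove(f)
                undecided.discard(f)
        if len(in_model) < 2:   # forest needs something to shadow against
            break

    dec = pd.DataFrame(
        {
            "status": [status[f] for f in feats],
            "hits": [hits[f] for f in feats],
            "n_tested": [tested[f] for f in feats],
            "importance_mean": [
                float(np.mean(imp_hist[f])) if imp_hist[f] else np.nan for f in feats
            ],
            "importance_sd": [
                float(np.std(imp_hist[f])) if len(imp_hist[f]) > 1 else np.nan
                for f in feats
            ],
        },
        index=pd.Index(feats, name="feature"),
    )
    return BorutaResult(decisions=dec, n_iter=it, seed=seed)


def boruta_consensus(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    **kwargs,
) -> pd.DataFrame:
    """Run Boruta once per seed; keep features confirmed in *every* run.

    Returns one row per feature with per-seed statuses, pooled importance
    mean/sd, and the ``consensus`` flag (confirmed under all seeds). An
    empty consensus is a legitimate outcome.
    """
    runs = [boruta(X, y, seed=s, **kwargs) for s in seeds]
    feats = list(pd.DataFrame(X).columns)
    out = pd.DataFrame(index=pd.Index(feats, name="feature"))
    for s, r in zip(seeds, runs):
        out[f"status_seed{s}"] = r.decisions["status"]
    imp = np.column_stack([r.decisions["importance_mean"] for r in runs])
    out["importance_mean"] = np.nanmean(imp, axis=1)
    out["importance_sd"] = np.nanstd(imp, axis=1)
    status_cols = [f"status_seed{s}" for s in seeds]
    out["consensus"] = (out[status_cols] == "confirmed").all(axis=1)
    return out
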