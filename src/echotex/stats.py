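"""Cohort statistics: Spearman grids, Fisher-z averaging, EM imputation,
Little's MCAR test, standardized GLM, variance explained, and ICC.

The analysis this package models ranks texture features by averaging each
feature's Spearman correlations with five function tests on the Fisher-z
scale: r -> z' = artanh(r), mean the z' values, back-transform with tanh.
artanh is approximately variance-stabilizing for correlation coefficients,
so averaging on that scale avoids the bias of averaging r directly.

Missing data is handled the way the modeled workflow does: Little's MCAR
test for the missingness pattern, then expectation-maximization under a
multivariate-normal working model with deterministic conditional-mean
fill for the covariates entering the GLM; correlations use pairwise
deletion instead of imputed values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from . import reference

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationCell", "AggregateCorrelation", "CorrelationTable",
    "LittleMCARResult", "PredictorResult", "ReliabilityResult",
    "DomainError", "CollinearityError",
    "spearman", "fisher_z", "inverse_fisher_z", "average_correlations",
    "little_mcar_test", "EMImputer", "em_impute",
    "StandardizedGLM", "standardized_glm", "variance_explained",
    "icc_reliability", "build_correlation_table",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of the operation."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix; names the aliased columns."""


# ---------------------------------------------------------------------------
# correlation primitives

@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman coefficient with its two-sided p and pair count.

    ``rho`` and ``p_value`` are NaN when the correlation is undefined
    (fewer than 3 complete pairs, or zero rank variance).
    """

    rho: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def spearman(x, y, *, method: str = "t") -> CorrelationCell:
    """Spearman rank correlation with pairwise deletion of missing values.

    Ties get average ranks; rho is the Pearson correlation of the ranks;
    the two-sided p comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df
    (``method="t"``), or from a pairing permutation test
    (``method="permutation"``, intended for very small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationCell(math.nan, math.nan, n)
    if method == "t":
        rho, p = sps.spearmanr(x, y)
        return CorrelationCell(float(rho), float(p), n)
    if method == "permutation":
        res = sps.permutation_test(
            (x, y), lambda a, b: sps.spearmanr(a, b).statistic,
            permutation_type="pairings", n_resamples=9999,
            alternative="two-sided", random_state=0)
        return CorrelationCell(float(res.statistic), float(res.pvalue), n)
    raise ValueError(f"unknown method {method!r}")


def fisher_z(r: float) -> float:
    """Fisher z-transform z' = artanh(r); requires |r| < 1."""
    if abs(r) >= 1.0:
        raise DomainError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    """Back-transform r = tanh(z')."""
    return float(np.tanh(z))


@dataclass(frozen=True)
class AggregateCorrelation:
    """Fisher-z average of a set of correlation coefficients."""

    z_values: tuple[float, ...]
    mean_z: float
    r_back: float

    @property
    def r_rounded(self) -> float:
        """r_back at report precision (3 decimals, round-half-even)."""
        return round(self.r_back, 3)


def average_correlations(rhos) -> AggregateCorrelation:
    """Average coefficients on the Fisher-z scale, back-transform with tanh."""
    rhos = [float(r) for r in rhos]
    if not rhos:
        raise DomainError("cannot average an empty coefficient list")
    z = tuple(fisher_z(r) for r in rhos)
    mean_z = float(np.mean(z))
    return AggregateCorrelation(z_values=z, mean_z=mean_z,
                                r_back=inverse_fisher_z(mean_z))


# ---------------------------------------------------------------------------
# EM imputation under a multivariate-normal working model

class EMImputer(TransformerMixin, BaseEstimator):
    """Multivariate-normal EM with deterministic conditional-mean fill.

    ``fit`` runs EM on the observed entries to maximum-likelihood mean
    and covariance; ``transform`` fills each missing entry with its
    conditional expectation given the observed entries of the same row.
    The fill is deterministic (no residual draw), matching the imputation
    procedure of the modeled analysis; set ``add_noise=True`` for a
    seeded stochastic draw from the conditional distribution instead
    (sensitivity analyses only).

    Attributes
    ----------
    mean_ : (p,) ML mean
    covariance_ : (p, p) ML covariance
    n_iter_ : EM iterations used
    converged_ : whether the log-likelihood tolerance was met
    loglik_ : observed-data log-likelihood at the final iterate
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 200,
                 ridge: float = 1e-10, add_noise: bool = False,
                 random_state: int | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.add_noise = add_noise
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _patterns(mask: np.ndarray):
        """Group row indices by missingness pattern."""
        keys = {}
        for i, row in enumerate(mask):
            keys.setdefault(row.tobytes(), []).append(i)
        for key, idx in keys.items():
            pat = np.frombuffer(key, dtype=bool)
            yield pat, np.asarray(idx)

    def _e_step(self, X, mask, mu, sigma):
        n, p = X.shape
        filled = X.copy()
        s_xx = np.zeros((p, p))
        loglik = 0.0
        for pat, idx in self._patterns(mask):
            obs = ~pat
            miss = pat
            Xo = X[np.ix_(idx, np.flatnonzero(obs))]
            k = len(idx)
            soo = sigma[np.ix_(obs, obs)]
            if obs.sum() == 0:
                filled[np.ix_(idx, np.flatnonzero(miss))] = mu[miss]
                s_xx[np.ix_(miss, miss)] += k * (
                    sigma[np.ix_(miss, miss)] + np.outer(mu[miss], mu[miss]))
                continue
            try:
                chol = np.linalg.cholesky(soo)
                solve = lambda b: np.linalg.solve(
                    chol.T, np.linalg.solve(chol, b))
                logdet = 2.0 * np.log(np.diag(chol)).sum()
            except np.linalg.LinAlgError:
                warnings.warn("singular observed covariance block; using "
                              "pseudo-inverse", RuntimeWarning)
                pinv = np.linalg.pinv(soo)
                solve = lambda b: pinv @ b
                logdet = np.linalg.slogdet(soo + np.eye(int(obs.sum()))
                                           * self.ridge)[1]
            dev = Xo - mu[obs]
            mahal = np.einsum("ij,ij->i", dev, solve(dev.T).T)
            loglik += -0.5 * (k * (obs.sum() * math.log(2 * math.pi)
                                   + logdet) + mahal.sum())
            if miss.any():
                smo = sigma[np.ix_(miss, obs)]
                beta = solve(smo.T).T          # Sigma_mo Sigma_oo^-1
                cond = mu[miss] + dev @ beta.T
                filled[np.ix_(idx, np.flatnonzero(miss))] = cond
                c_mm = sigma[np.ix_(miss, miss)] - beta @ smo.T
                s_xx[np.ix_(miss, miss)] += k * c_mm
        s_xx += filled.T @ filled
        return filled, s_xx, loglik

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D numeric matrix")
        mask = np.isnan(X)
        n, p = X.shape
        obs_per_var = (~mask).sum(axis=0)
        if (obs_per_var < 2).any():
            bad = np.flatnonzero(obs_per_var < 2)
            raise ValueError(f"variables {bad.tolist()} observed fewer "
                             "than twice")
        mu = np.nanmean(X, axis=0)
        var = np.nanvar(X, axis=0)
        sigma = np.diag(np.maximum(var, 1e-12))
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            filled, s_xx, ll = self._e_step(X, mask, mu, sigma)
            mu = filled.mean(axis=0)
            sigma = s_xx / n - np.outer(mu, mu)
            sigma = (sigma + sigma.T) / 2.0
            eig_min = np.linalg.eigvalsh(sigma)[0]
            if eig_min <= 0:
                bump = abs(eig_min) + self.ridge * np.trace(sigma) / p
                logger.warning("EM covariance not PD; ridge %.3e added", bump)
                sigma += bump * np.eye(p)
            if it > 1 and ll - prev_ll < self.tol:
                self.converged_ = True
                prev_ll = ll
                break
            prev_ll = ll
        else:
            it = self.max_iter
            if mask.any():
                warnings.warn("EM did not reach tolerance; returning last "
                              "iterate", RuntimeWarning)
        self.mean_ = mu
        self.covariance_ = sigma
        self.n_iter_ = it
        self.loglik_ = prev_ll
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        filled, _, _ = self._e_step(X, mask, self.mean_, self.covariance_)
        if self.add_noise and mask.any():
            rng = np.random.default_rng(self.random_state)
            for pat, idx in self._patterns(mask):
                if not pat.any():
                    continue
                obs, miss = ~pat, np.flatnonzero(pat)
                soo = self.covariance_[np.ix_(obs, obs)]
                smo = self.covariance_[np.ix_(pat, obs)]
                beta = np.linalg.solve(soo, smo.T).T
                c_mm = self.covariance_[np.ix_(pat, pat)] - beta @ smo.T
                c_mm = (c_mm + c_mm.T) / 2.0
                draw = rng.multivariate_normal(
                    np.zeros(len(miss)), c_mm, size=len(idx),
                    method="eigh")
                filled[np.ix_(idx, miss)] += draw
        return filled


def em_impute(X, *, tol: float = 1e-6, max_iter: int = 200):
    """EM-impute a numeric matrix; returns (completed, imputer).

    ``completed`` fills missing entries with conditional means under the
    fitted multivariate normal; the fitted :class:`EMImputer` exposes
    ``mean_`` and ``covariance_`` (maximum-likelihood moments).
    """
    imp = EMImputer(tol=tol, max_iter=max_iter).fit(X)
    return imp.transform(X), imp


# ---------------------------------------------------------------------------
# Little's MCAR test

@dataclass(frozen=True)
class LittleMCARResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int


def little_mcar_test(X, *, tol: float = 1e-6,
                     max_iter: int = 200) -> LittleMCARResult:
    """Little's chi-square test of the MCAR hypothesis.

    Compares each missingness pattern's observed-variable means against
    the EM (maximum-likelihood) estimates:
    d^2 = sum_j n_j (ybar_j - mu_obs_j)' Sigma_obs_j^{-1} (ybar_j - mu_obs_j),
    referred to chi-square with df = sum_j p_j - p. A small p-value is
    evidence against "missing completely at random".
    """
    X = np.asarray(X, dtype=float)
    mask = np.isnan(X)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 numeric variables")
    _, imp = em_impute(X, tol=tol, max_iter=max_iter)
    mu, sigma = imp.mean_, imp.covariance_
    d2 = 0.0
    df = 0
    n_patterns = 0
    for pat, idx in EMImputer._patterns(mask):
        obs = np.flatnonzero(~pat)
        if obs.size == 0:
            continue
        n_patterns += 1
        df += obs.size
        ybar = X[np.ix_(idx, obs)].mean(axis=0)
        dev = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        try:
            d2 += len(idx) * float(dev @ np.linalg.solve(soo, dev))
        except np.linalg.LinAlgError:
            warnings.warn("singular observed covariance in Little's test; "
                          "pseudo-inverse used", RuntimeWarning)
            d2 += len(idx) * float(dev @ np.linalg.pinv(soo) @ dev)
    df -= p
    p_value = 1.0 if df <= 0 else float(sps.chi2.sf(d2, df))
    return LittleMCARResult(statistic=d2, df=max(df, 0), p_value=p_value,
                            n_patterns=n_patterns)


# ---------------------------------------------------------------------------
# standardized GLM

@dataclass(frozen=True)
class PredictorResult:
    name: str
    beta: float
    t_stat: float
    p_value: float


class StandardizedGLM(BaseEstimator):
    """OLS on z-scored outcome and predictors (fully standardized betas).

    ``fit(X, y)`` z-scores every column of X and y, then fits ordinary
    least squares with an intercept; ``coef_`` are the standardized
    coefficients, with t statistics on n - k - 1 residual df. Binary and
    categorical predictors must be numerically coded before entry (see
    :func:`standardized_glm` for the cohort-specific coding).
    """

    def fit(self, X, y):
        import statsmodels.api as sm

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float)
        n, k = Xa.shape
        if n <= k + 1:
            raise ValueError(f"need n > k + 1 (n={n}, k={k})")
        sds = Xa.std(axis=0, ddof=1)
        if (sds == 0).any():
            dead = [names[i] for i in np.flatnonzero(sds == 0)]
            raise CollinearityError(f"constant predictor columns: {dead}")
        Z = (Xa - Xa.mean(axis=0)) / sds
        rank = np.linalg.matrix_rank(Z)
        if rank < k:
            from scipy.linalg import qr
            _, r, piv = qr(Z, pivoting=True)
            aliased = sorted(names[i] for i in piv[rank:])
            raise CollinearityError(f"collinear predictor columns: {aliased}")
        zy = (ya - ya.mean()) / ya.std(ddof=1)
        res = sm.OLS(zy, sm.add_constant(Z)).fit()
        self.feature_names_in_ = names
        self.coef_ = res.params[1:]
        self.tvalues_ = res.tvalues[1:]
        self.pvalues_ = res.pvalues[1:]
        self.bse_ = res.bse[1:]
        self.df_resid_ = int(res.df_resid)
        self.rsquared_ = float(res.rsquared)
        return self

    def predict(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        Z = (Xa - Xa.mean(axis=0)) / Xa.std(axis=0, ddof=1)
        return Z @ self.coef_

    def results(self) -> list[PredictorResult]:
        return [PredictorResult(n, float(b), float(t), float(p))
                for n, b, t, p in zip(self.feature_names_in_, self.coef_,
                                      self.tvalues_, self.pvalues_)]


GLM_PREDICTORS = ("age", "sex", "ethnicity", "egfr", "hb", "albumin", "bmi")


def encode_glm_predictors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the standard predictor set.

    sex: female=0, male=1; ethnicity collapsed to a White / non-White
    indicator (non-White=0, White=1). Continuous predictors pass through.
    """
    out = pd.DataFrame(index=cohort.index)
    for col in GLM_PREDICTORS:
        s = cohort[col]
        if col == "sex":
            out[col] = (s.astype(str).str.lower()
                        .map({"male": 1.0, "female": 0.0, "1": 1.0,
                              "0": 0.0, "m": 1.0, "f": 0.0}))
        elif col == "ethnicity":
            out[col] = (s.astype(str).str.lower() == "white").astype(float)
            out.loc[s.isna(), col] = np.nan
        else:
            out[col] = pd.to_numeric(s, errors="coerce")
    return out


def standardized_glm(outcome, predictors: pd.DataFrame) -> list[PredictorResult]:
    """Standardized betas, t and p of each predictor for one outcome."""
    model = StandardizedGLM().fit(predictors, outcome)
    return model.results()


def variance_explained(outcome, features: pd.DataFrame) -> float:
    """Multiple R^2 of the outcome on the texture features jointly.

    The texture features are strongly mutually correlated, so the design
    can be badly conditioned; the condition number is logged, and exactly
    duplicated (aliased) columns are dropped with a warning rather than
    failing the fit.
    """
    import statsmodels.api as sm

    Xa = features.to_numpy(dtype=float)
    names = list(features.columns)
    ya = np.asarray(outcome, dtype=float)
    keep = np.ones(Xa.shape[1], dtype=bool)
    rank = np.linalg.matrix_rank(Xa - Xa.mean(axis=0))
    if rank < Xa.shape[1]:
        from scipy.linalg import qr
        _, r, piv = qr(Xa - Xa.mean(axis=0), pivoting=True)
        for i in piv[rank:]:
            keep[i] = False
        warnings.warn(f"aliased feature columns dropped: "
                      f"{[names[i] for i in np.flatnonzero(~keep)]}",
                      RuntimeWarning)
    Xk = sm.add_constant(Xa[:, keep])
    res = sm.OLS(ya, Xk).fit()
    logger.info("variance_explained: condition number %.3g",
                np.linalg.cond(Xk))
    return float(res.rsquared)


# ---------------------------------------------------------------------------
# reliability

@dataclass(frozen=True)
class ReliabilityResult:
    """Test-retest agreement between two measurement passes.

    ``icc`` is ICC(2,1) — two-way random effects, absolute agreement,
    single measurement; ``icc_consistency`` is ICC(3,1), which ignores a
    constant shift between passes. ``diff_p`` is the paired t-test p for
    a systematic difference.
    """

    icc: float
    icc_consistency: float
    diff_p: float
    model_label: str = "ICC(2,1) two-way random, absolute agreement"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.icc)


def icc_reliability(measure1, measure2) -> ReliabilityResult:
    """ICC and paired-difference p for two repeated measurement passes."""
    m1 = np.asarray(measure1, dtype=float)
    m2 = np.asarray(measure2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("measures must be equal-length 1-D arrays")
    keep = ~(np.isnan(m1) | np.isnan(m2))
    m1, m2 = m1[keep], m2[keep]
    n = m1.size
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    Y = np.column_stack([m1, m2])
    k = 2
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or (msr == mse == msc == 0):
        return ReliabilityResult(math.nan, math.nan, math.nan)
    denom_abs = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_abs = (msr - mse) / denom_abs if denom_abs > 0 else math.nan
    denom_con = msr + (k - 1) * mse
    icc_con = (msr - mse) / denom_con if denom_con > 0 else math.nan
    diffs = m1 - m2
    if np.ptp(diffs) == 0:  # zero-variance differences: t undefined
        diff_p = 1.0 if diffs[0] == 0 else 0.0
    else:
        diff_p = float(sps.ttest_rel(m1, m2).pvalue)
    return ReliabilityResult(float(icc_abs), float(icc_con), diff_p)


# ---------------------------------------------------------------------------
# correlation table

@dataclass
class CorrelationTable:
    """Feature x test Spearman grid plus Fisher-z average per feature."""

    cells: dict[tuple[str, str], CorrelationCell]
    aggregates: dict[str, AggregateCorrelation]
    best_feature: str
    tests: tuple[str, ...] = field(default=reference.TEST_NAMES)
    features: tuple[str, ...] = field(default=reference.FEATURE_NAMES)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            row: dict[str, float] = {"feature": f}
            for t in self.tests:
                cell = self.cells.get((f, t))
                row[f"{t}_rho"] = cell.rho if cell else math.nan
                row[f"{t}_p"] = cell.p_value if cell else math.nan
            agg = self.aggregates.get(f)
            row["average_r"] = agg.r_back if agg else math.nan
            rows.append(row)
        return pd.DataFrame(rows)


def build_correlation_table(cohort: pd.DataFrame, *,
                            features=reference.FEATURE_NAMES,
                            tests=reference.TEST_NAMES) -> CorrelationTable:
    """Spearman grid of texture features against function tests.

    Pairwise deletion per cell; a test column that is entirely missing is
    skipped with a warning. Each feature's coefficients are averaged on
    the Fisher-z scale, and the feature with the largest |average| is
    flagged.
    """
    usable = []
    for t in tests:
        if t not in cohort.columns or cohort[t].notna().sum() == 0:
            warnings.warn(f"function test {t!r} entirely missing; skipped",
                          RuntimeWarning)
            continue
        usable.append(t)
    if not usable:
        raise ValueError("no usable function-test columns")
    cells = {}
    aggregates = {}
    for f in features:
        rhos = []
        for t in usable:
            cell = spearman(cohort[f], cohort[t])
            cells[(f, t)] = cell
            if not cell.defined:
                continue
            if abs(cell.rho) >= 1.0:
                # |rho| = 1 has infinite Fisher z; cap just inside the
                # domain so a degenerate cell cannot poison the average
                warnings.warn(f"|rho|=1 for ({f}, {t}); capped for "
                              "Fisher averaging", RuntimeWarning)
                rhos.append(math.copysign(0.999999, cell.rho))
            else:
                rhos.append(cell.rho)
        if rhos:
            aggregates[f] = average_correlations(rhos)
    if aggregates:
        best = max(aggregates, key=lambda f: abs(aggregates[f].r_back))
    else:
        warnings.warn("no defined correlation in the grid", RuntimeWarning)
        best = None
    return CorrelationTable(cells=cells, aggregates=aggregates,
                            best_feature=best, tests=tuple(usable),
                            features=tuple(features))
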