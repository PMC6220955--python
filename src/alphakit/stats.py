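"""Inference battery for the alpha-entrainment analyses.

Implements, on top of plain arrays / tidy DataFrames:

* cluster-based permutation statistics on sensor topographies
  (Delaunay-triangulation neighbourhoods, paired t, within-subject
  sign-flip null with the maximum-cluster statistic);
* repeated-measures ANOVA for fully crossed within-subject designs with
  Greenhouse-Geisser correction and partial omega squared;
* JZS Bayes-factor ANOVA (g-priors on standardized effects, fixed-effect
  scale r = 0.5, subject block integrated out under a flat prior,
  Monte-Carlo marginal likelihoods with a reported proportional error);
* robust linear regression (IRLS with bisquare weights, tuning 4.685)
  with Cook's-distance outlier screening;
* BCa bootstrap confidence intervals and Bonferroni-adjusted
  slope-difference tests;
* Friedman test, logit transform, Holm-Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from scipy.spatial import Delaunay
from statsmodels.stats.multitest import multipletests

from .synth_eeg import Montage

__all__ = [
    "ClusterTestResult",
    "AnovaResult",
    "BayesAnovaResult",
    "RegressionFit",
    "FriedmanResult",
    "cluster_permutation_test",
    "triangulation_neighbors",
    "rm_anova_gg",
    "jzs_anova_bf",
    "jzs_ttest_bf",
    "robust_fit",
    "robust_line",
    "cooks_outlier_removal",
    "bca_bootstrap_ci",
    "slope_difference_test",
    "friedman_test",
    "logit_transform",
    "holm_bonferroni",
]


# --------------------------------------------------------------------------
# cluster-based permutation statistics
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    channels: list                 # channel indices
    stat: float                    # signed sum of paired t values
    p: float                       # two-sided corrected permutation p


@dataclass
class ClusterTestResult:
    clusters: list                 # list[Cluster], sorted by |stat| descending
    n_perm: int
    mean_degree: float             # of the neighbour graph
    t_obs: np.ndarray              # per-channel paired t

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _azimuthal_projection(pos: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection of unit-sphere positions from the
    vertex; preserves neighbourhood structure for Delaunay triangulation."""
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    az = np.arctan2(pos[:, 1], pos[:, 0])
    return np.stack([theta * np.cos(az), theta * np.sin(az)], axis=1)


def triangulation_neighbors(montage: Montage) -> list[set]:
    """Channel neighbourhoods from Delaunay triangulation of the planar
    projection of the 3-D electrode positions."""
    plane = _azimuthal_projection(montage.pos)
    tri = Delaunay(plane)
    nbrs: list[set] = [set() for _ in range(montage.n_channels)]
    for simplex in tri.simplices:
        for a, b in combinations(simplex, 2):
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
    return nbrs


def _components(channels: np.ndarray, nbrs: list[set]) -> list[list[int]]:
    """Connected components of a channel subset under the neighbour graph."""
    chanset = set(int(c) for c in channels)
    seen: set[int] = set()
    comps = []
    for c in chanset:
        if c in seen:
            continue
        comp, stack = [], [c]
        seen.add(c)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in nbrs[u]:
                if v in chanset and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t per channel; zero-variance channels get t = 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _max_cluster_sums(t: np.ndarray, tcrit: float, nbrs: list[set]
                      ) -> tuple[float, float]:
    """(max positive cluster sum, max |negative cluster sum|) for one map."""
    pos_max = neg_max = 0.0
    sup = np.flatnonzero(t > tcrit)
    if sup.size:
        pos_max = max(float(t[comp].sum()) for comp in _components(sup, nbrs))
    sub = np.flatnonzero(t < -tcrit)
    if sub.size:
        neg_max = max(float(-t[comp].sum()) for comp in _components(sub, nbrs))
    return pos_max, neg_max


def cluster_permutation_test(topo_A: np.ndarray, topo_B: np.ndarray,
                             montage: Montage, n_perm: int = 1000,
                             cluster_alpha: float = 0.05,
                             seed: int = 0) -> ClusterTestResult:
    """Paired two-condition cluster permutation test on sensor topographies.

    ``topo_A``/``topo_B``: (n_subjects, n_channels).  Channels whose paired
    t exceeds the two-tailed ``cluster_alpha`` threshold are clustered by
    triangulation-neighbourhood connectivity; each cluster's summed t is
    referred to the maximum-cluster null distribution obtained from
    within-subject sign flips of the condition difference, and the
    permutation p is doubled (capped at 1) to correct for two-sided testing.
    """
    A = np.asarray(topo_A, dtype=float)
    B = np.asarray(topo_B, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("topographies must both be (n_subjects, n_channels)")
    n_subj, n_chan = A.shape
    if n_subj < 6:
        raise ValueError("need at least 6 subjects")
    if n_chan != montage.n_channels:
        raise ValueError("topography/montage channel mismatch")
    nbrs = triangulation_neighbors(montage)
    mean_degree = float(np.mean([len(s) for s in nbrs]))

    D = A - B
    t_obs = _paired_t(D)
    tcrit = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, n_subj - 1))

    clusters: list[Cluster] = []
    sup = np.flatnonzero(t_obs > tcrit)
    obs = [(comp, float(t_obs[comp].sum()), +1)
           for comp in _components(sup, nbrs)] if sup.size else []
    sub = np.flatnonzero(t_obs < -tcrit)
    obs += [(comp, float(t_obs[comp].sum()), -1)
            for comp in _components(sub, nbrs)] if sub.size else []

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # sign flips leave per-channel E[d^2] untouched: t fully vectorized
    m_perm = signs @ D / n_subj
    e2 = np.mean(D**2, axis=0)
    var = (e2[None, :] - m_perm**2) * n_subj / (n_subj - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m_perm / np.sqrt(var / n_subj)
    t_perm[~np.isfinite(t_perm)] = 0.0

    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    any_sup = np.abs(t_perm).max(axis=1) > tcrit
    for k in np.flatnonzero(any_sup):
        null_pos[k], null_neg[k] = _max_cluster_sums(t_perm[k], tcrit, nbrs)

    for comp, stat, sign in obs:
        null = null_pos if sign > 0 else null_neg
        p = (1 + np.sum(null >= abs(stat))) / (n_perm + 1)
        clusters.append(Cluster(channels=comp, stat=stat,
                                p=float(min(1.0, 2.0 * p))))
    clusters.sort(key=lambda c: -abs(c.stat))
    return ClusterTestResult(clusters=clusters, n_perm=n_perm,
                             mean_degree=mean_degree, t_obs=t_obs)


# --------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse-Geisser correction
# --------------------------------------------------------------------------

@dataclass
class AnovaEffect:
    F: float
    df: tuple                      # (df_effect, df_error), uncorrected
    p: float
    p_gg: float
    epsilon_gg: float
    omega_p2: float
    omega_truncated: bool = False


@dataclass
class AnovaResult:
    effects: dict                  # effect name -> AnovaEffect
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({"effect": name, "F": e.F, "df1": e.df[0], "df2": e.df[1],
                         "p": e.p, "p_gg": e.p_gg, "epsilon_gg": e.epsilon_gg,
                         "omega_p2": e.omega_p2})
        return pd.DataFrame(rows)


def _cell_matrix(data: pd.DataFrame, dv: str, subject: str, within: list[str]
                 ) -> tuple[np.ndarray, list, list]:
    """Pivot a tidy table to (subjects × cells); error on unbalanced data."""
    levels = [sorted(data[f].unique()) for f in within]
    cells = list(product(*levels))
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean")
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    if counts.min() < 1 or wide.isna().any().any():
        raise ValueError("design must be balanced and complete (no missing cells)")
    if len(within) == 1:
        order = [c[0] for c in cells]
    else:
        order = cells
    Y = wide[order].to_numpy(dtype=float)
    return Y, levels, cells


def rm_anova_gg(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                within: list[str] | None = None) -> AnovaResult:
    """Fully within-subject ANOVA with GG correction and partial omega².

    Every main effect and interaction of the ``within`` factors is tested
    with the standard subject-by-effect error stratum.  Greenhouse-Geisser
    epsilon is estimated from the covariance of the orthonormalized
    factor-level differences (exactly 1 for single-df effects) and applied
    to the degrees of freedom for ``p_gg``.  Partial omega squared uses
    ω²p = df·(F−1) / (df·(F−1) + df + df_err + 1), truncated at 0.
    """
    if within is None:
        raise ValueError("within factors must be named")
    Y, levels, _ = _cell_matrix(data, dv, subject, within)
    n = Y.shape[0]
    contrasts = [helmert(len(lv), full=False).T for lv in levels]  # a×(a−1)
    ones = [np.ones((len(lv), 1)) / len(lv) for lv in levels]

    effects: dict[str, AnovaEffect] = {}
    m = len(within)
    for r in range(1, m + 1):
        for combo in combinations(range(m), r):
            K = np.ones((1, 1))
            for f in range(m):
                K = np.kron(K, contrasts[f] if f in combo else ones[f])
            D = Y @ K                                   # subjects × q
            q = D.shape[1]
            dbar = D.mean(axis=0)
            ss_eff = n * float(dbar @ dbar)
            resid = D - dbar
            ss_err = float((resid**2).sum())
            df1, df2 = q, q * (n - 1)
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
            if q == 1:
                eps = 1.0
            else:
                S = np.cov(D, rowvar=False)
                eps = float(np.trace(S) ** 2 / (q * np.trace(S @ S)))
                eps = min(1.0, max(eps, 1.0 / q))
            p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
            w_num = df1 * (F - 1.0)
            omega = w_num / (w_num + df1 + df2 + 1.0)
            truncated = omega < 0
            name = ":".join(within[f] for f in combo)
            effects[name] = AnovaEffect(F=float(F), df=(df1, df2), p=p,
                                        p_gg=p_gg, epsilon_gg=eps,
                                        omega_p2=max(0.0, float(omega)),
                                        omega_truncated=truncated)
    return AnovaResult(effects=effects, n_subjects=n)


# --------------------------------------------------------------------------
# JZS Bayes-factor ANOVA
# --------------------------------------------------------------------------

@dataclass
class BayesEffect:
    bf10: float
    mc_error_pct: float            # proportional Monte-Carlo error, %
    flagged: bool = False          # True when the MC error exceeds 5%

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass
class BayesAnovaResult:
    effects: dict                  # effect name -> BayesEffect
    n_mc: int
    r_fixed: float


def _effect_design(data: pd.DataFrame, within: list[str],
                   levels: list, combo: tuple) -> np.ndarray:
    """Orthonormal-contrast design matrix (N × q) for one effect."""
    N = len(data)
    X = np.ones((N, 1))
    for f in combo:
        C = helmert(len(levels[f]), full=False).T        # a × (a−1)
        idx = pd.Categorical(data[within[f]], categories=levels[f]).codes
        X = (X[:, :, None] * C[idx][:, None, :]).reshape(N, -1)
    return X


def _bf_mc(y: np.ndarray, M: np.ndarray, X: np.ndarray, d: int,
           r: float, n_mc: int, rng: np.random.Generator
           ) -> tuple[float, float]:
    """BF10 and proportional MC error for one g-prior effect block.

    Marginal likelihood ratio against the nuisance-only model, integrating
    the JZS prior g ~ InvGamma(1/2, r²/2) by Monte Carlo; everything else
    is closed form after projecting out the nuisance block (M = I − P_Z).
    """
    u2 = float(y @ M @ y)
    WtW = X.T @ M @ X
    Wty = X.T @ M @ y
    lam, V = np.linalg.eigh(WtW)
    lam = np.clip(lam, 0.0, None)
    s2 = (V.T @ Wty) ** 2
    g = 1.0 / rng.gamma(0.5, scale=2.0 / r**2, size=n_mc)
    glam = np.outer(g, lam)                               # (n_mc, q)
    logdet = 0.5 * np.log1p(glam).sum(axis=1)
    # Woodbury: u'(I+gWW')⁻¹u = u'u − Σ_i s_i²·g/(1+gλ_i)
    Q = u2 - (g[:, None] / (1.0 + glam) * s2[None, :]).sum(axis=1)
    logR = -logdet - 0.5 * d * (np.log(Q) - np.log(u2))
    Rmax = logR.max()
    w = np.exp(logR - Rmax)
    bf = float(np.exp(Rmax) * w.mean())
    mc_err = float(w.std(ddof=1) / (w.mean() * np.sqrt(n_mc)))
    return bf, 100.0 * mc_err


def jzs_anova_bf(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                 within: list[str] | None = None, r_fixed: float = 0.5,
                 n_mc: int = 100_000, seed: int = 0) -> BayesAnovaResult:
    """Per-term JZS Bayes factors for a balanced within-subject design.

    For each main effect and interaction, BF10 compares the model
    {intercept + subject + effect} against {intercept + subject}.  The
    subject block is integrated out under a noninformative flat prior (so a
    single two-level factor reduces exactly to the one-sample JZS t Bayes
    factor on the paired differences); standardized effects carry a
    mixture-of-g (JZS) prior with scale ``r_fixed``.  BF10 is scale
    invariant in the data.  The Monte-Carlo integral over g uses ``n_mc``
    draws; results with proportional error above 5% are flagged.
    """
    if within is None:
        raise ValueError("within factors must be named")
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 1e4")
    _cell_matrix(data, dv, subject, within)   # balance check
    data = data.sort_values([subject] + within).reset_index(drop=True)
    levels = [sorted(data[f].unique()) for f in within]
    y = data[dv].to_numpy(dtype=float)
    N = y.size
    subj_codes = np.asarray(pd.Categorical(data[subject]).codes, dtype=int)
    n_subj = int(subj_codes.max()) + 1
    Z = np.zeros((N, n_subj))
    Z[np.arange(N), subj_codes] = 1.0         # spans the intercept too
    M = np.eye(N) - Z @ np.linalg.pinv(Z)
    d = N - n_subj

    rng = np.random.default_rng(seed)
    m = len(within)
    effects: dict[str, BayesEffect] = {}
    for r_ in range(1, m + 1):
        for combo in combinations(range(m), r_):
            X = _effect_design(data, within, levels, combo)
            bf, err = _bf_mc(y, M, X, d, r_fixed, n_mc, rng)
            name = ":".join(within[f] for f in combo)
            effects[name] = BayesEffect(bf10=bf, mc_error_pct=err,
                                        flagged=err > 5.0)
    return BayesAnovaResult(effects=effects, n_mc=n_mc, r_fixed=r_fixed)


def jzs_ttest_bf(x: np.ndarray, r: float = 0.5) -> float:
    """Closed-form (quadrature) one-sample JZS Bayes factor.

    Independent numerical-integration route for cross-checking the MC
    Bayes-factor ANOVA on a single two-level within factor: ``x`` holds the
    paired differences; the effect size δ carries a Cauchy(0, r) prior.
    """
    from scipy.integrate import quad
    x = np.asarray(x, dtype=float)
    n = x.size
    t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    nu = n - 1

    def integrand(g):
        return ((1 + n * g) ** -0.5
                * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
                * (2 * np.pi) ** -0.5 * r * g ** -1.5
                * np.exp(-r**2 / (2 * g)))

    num, _ = quad(integrand, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return float(num / den)


# --------------------------------------------------------------------------
# robust regression, Cook's distance, BCa bootstrap
# --------------------------------------------------------------------------

@dataclass
class RegressionFit:
    beta0: float
    beta1: float
    r2: float
    n: int
    outliers_removed: list = field(default_factory=list)
    f_stat: float = np.nan
    f_p: float = np.nan
    ci_beta0: tuple | None = None
    ci_beta1: tuple | None = None
    ci_level: float | None = None


def robust_line(x: np.ndarray, y: np.ndarray, tuning: float = 4.685,
                max_iter: int = 50, tol: float = 1e-9
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS straight-line fit with Tukey bisquare weights.

    Batched: ``x``/``y`` may be (..., n); returns (beta0, beta1, weights)
    with matching leading shape.  The robust scale is the MAD of the
    current residuals (consistency factor 0.6745), re-estimated each
    iteration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shapes")
    degenerate = np.ptp(x, axis=-1) == 0
    if x.ndim == 1 and degenerate:
        raise ValueError("x has zero variance")
    w = np.ones_like(x)
    b0 = np.zeros(x.shape[:-1])
    b1 = np.zeros(x.shape[:-1])
    for _ in range(max_iter):
        sw = w.sum(axis=-1)
        xw = (w * x).sum(axis=-1) / sw
        yw = (w * y).sum(axis=-1) / sw
        dx = x - xw[..., None]
        dy = y - yw[..., None]
        denom = (w * dx * dx).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            b1_new = (w * dx * dy).sum(axis=-1) / denom
        # degenerate batch members (zero x-spread in a resample) -> flat line
        b1_new = np.where(denom > 0, b1_new, 0.0)
        b0_new = yw - b1_new * xw
        resid = y - b0_new[..., None] - b1_new[..., None] * x
        med = np.median(resid, axis=-1, keepdims=True)
        mad = np.median(np.abs(resid - med), axis=-1, keepdims=True)
        scale = np.maximum(mad / 0.6745, 1e-12)
        u = resid / (tuning * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # guard: if everything got zero weight, fall back to OLS weights
        dead = w.sum(axis=-1) < 2
        if np.any(dead):
            w[dead] = 1.0
        if np.max(np.abs(b1_new - b1)) < tol and np.max(np.abs(b0_new - b0)) < tol:
            b0, b1 = b0_new, b1_new
            break
        b0, b1 = b0_new, b1_new
    return b0, b1, w


def cooks_outlier_removal(x: np.ndarray, y: np.ndarray,
                          threshold: float | None = None
                          ) -> tuple[np.ndarray, np.ndarray, list]:
    """Drop points whose Cook's distance from an ordinary fit exceeds the
    threshold (default 4/n)."""
    import statsmodels.api as sm
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if threshold is None:
        threshold = 4.0 / n
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = ols.get_influence().cooks_distance[0]
    removed = np.flatnonzero(cooks > threshold)
    keep = np.setdiff1d(np.arange(n), removed)
    return x[keep], y[keep], [int(i) for i in removed]


def robust_fit(x: np.ndarray, y: np.ndarray, remove_outliers: bool = True,
               cooks_threshold: float | None = None,
               tuning: float = 4.685) -> RegressionFit:
    """Robust straight-line regression with Cook's-distance screening.

    Cook's distances are computed from an ordinary least-squares fit and
    gross points removed (default threshold 4/n) before the IRLS bisquare
    fit.  R² and the F test against the constant model are evaluated with
    the converged robust weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    removed: list = []
    if remove_outliers:
        x, y, removed = cooks_outlier_removal(x, y, cooks_threshold)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 points after outlier removal")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    b0, b1, w = robust_line(x, y, tuning=tuning)
    b0, b1 = float(b0), float(b1)
    yw = float((w * y).sum() / w.sum())
    xw = float((w * x).sum() / w.sum())
    resid = y - b0 - b1 * x
    sse = float((w * resid**2).sum())
    sst = float((w * (y - yw) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    ssr = float(b1**2 * (w * (x - xw) ** 2).sum())
    if sse > 0:
        f = (ssr / 1.0) / (sse / (n - 2))
        f_p = float(sps.f.sf(f, 1, n - 2))
    else:                       # perfect fit (e.g. grid-quantized duplicates)
        f, f_p = np.inf, 0.0
    return RegressionFit(beta0=b0, beta1=b1, r2=float(r2), n=n,
                         outliers_removed=removed, f_stat=float(f), f_p=f_p)


def bca_bootstrap_ci(statistic_fn, data: tuple, n_boot: int = 10_000,
                     level: float = 0.95, seed: int = 0,
                     vectorized: bool = False) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI on paired samples.

    ``data`` is a tuple of equal-length arrays resampled jointly (subjects
    with replacement).  Degenerate bootstrap distributions (all resampled
    statistics equal) collapse to a point-mass interval.
    """
    data = tuple(np.asarray(a, dtype=float) for a in data)
    point = statistic_fn(*data) if not vectorized \
        else float(np.asarray(statistic_fn(*data, axis=-1)))
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.bootstrap(data, statistic_fn, n_resamples=n_boot,
                                paired=True, vectorized=vectorized,
                                confidence_level=level, method="BCa",
                                rng=np.random.default_rng(seed))
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    except Exception:
        lo = hi = np.nan
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return (float(point), float(point))
    return (lo, hi)


def slope_difference_test(xa, ya, xb, yb, n_boot: int = 10_000,
                          level: float = 1.0 - 0.05 / 3, seed: int = 0
                          ) -> dict:
    """BCa CI of the robust-slope difference between two paired conditions.

    Subjects are resampled jointly across both condition pairs; the default
    confidence level 1 − 0.05/3 Bonferroni-adjusts for the three pairwise
    band comparisons.  H0 (equal slopes) is rejected iff the CI excludes 0.
    """
    def stat(xa_, ya_, xb_, yb_, axis=-1):
        _, s1, _ = robust_line(np.moveaxis(xa_, axis, -1), np.moveaxis(ya_, axis, -1))
        _, s2, _ = robust_line(np.moveaxis(xb_, axis, -1), np.moveaxis(yb_, axis, -1))
        return s1 - s2

    delta = float(stat(np.asarray(xa), np.asarray(ya),
                       np.asarray(xb), np.asarray(yb)))
    ci = bca_bootstrap_ci(stat, (xa, ya, xb, yb), n_boot=n_boot, level=level,
                          seed=seed, vectorized=True)
    return {"delta_beta1": delta, "ci": ci, "level": level,
            "reject": not (ci[0] <= 0.0 <= ci[1])}


# --------------------------------------------------------------------------
# Friedman test, logit transform, Holm-Bonferroni
# --------------------------------------------------------------------------

@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p: float


def friedman_test(values: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a complete block design (subjects × k).

    Ties are handled by midranks with the usual tie correction; the fully
    tied degenerate case returns statistic 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    if np.all(np.ptp(values, axis=1) == 0):
        return FriedmanResult(statistic=0.0, df=k - 1, p=1.0)
    stat, p = sps.friedmanchisquare(*values.T)
    return FriedmanResult(statistic=float(stat), df=k - 1, p=float(p))


def logit_transform(p, n_trials: int | None = None) -> np.ndarray:
    """Logit of a proportion, clipped to [1/(2n), 1 − 1/(2n)] when the trial
    count is known (avoids infinities at 0 and 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    eps = 1.0 / (2 * n_trials) if n_trials else 1e-8
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (reject flags, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                        alpha=alpha, method="holm")
    return reject, p_adj
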