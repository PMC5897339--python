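"""Network-biased differential expression with empirical-Bayes moderation.

The analysis asks, gene by gene, whether expression in one functional network
exceeds expression in all the others. Expression is first aggregated
hierarchically — samples averaged within parcels, parcel means averaged
(unweighted) within networks, separately per donor — so each donor contributes
one observation per network. A one-vs-rest linear model is then fitted per
gene across the donor x network observations, with three choices for handling
the repeated-measures structure (observations from the same donor co-vary):

``none``
    ordinary least squares, ignoring donors;
``donor_fixed``
    donor indicator columns in the design;
``consensus_correlation``
    a single intra-donor correlation, pooled across genes, is estimated from
    per-gene one-way ANOVA ICCs of the residuals and used as a
    compound-symmetric block correlation in generalized least squares (the
    duplicate-correlation approach).

Per-gene residual variances are shrunk toward a pooled prior: the prior
(d0, s0^2) of a scaled-inverse-chi-square model is estimated by method of
moments on log s_g^2 using digamma/trigamma relations, and the moderated
variance is the posterior mean s~^2 = (d0 s0^2 + d s^2) / (d0 + d). The
moderated t-statistic has d0 + d degrees of freedom. Significance is
controlled with Benjamini-Hochberg FDR; the network-biased gene set is the
genes with q <= 0.01 and positive log2 fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .expression_io import ExpressionMatrix, ValueScale

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene", "network", "log2FC", "avg_expr", "t", "df", "p", "q")


# ---------------------------------------------------------------------------
# Aggregation: samples -> parcels -> networks, per donor
# ---------------------------------------------------------------------------


@dataclass
class NetworkExpression:
    """Donor x network mean expression, with parcel counts.

    ``values`` is a DataFrame indexed by a (donor, network) MultiIndex with one
    column per gene. A donor-network combination with no samples has no row
    (absent, never zero). ``parcel_counts`` records how many parcels
    contributed to each donor-network mean.
    """

    values: pd.DataFrame
    parcel_counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.index.names) != ["donor", "network"]:
            raise ValueError("values must be indexed by (donor, network)")

    @property
    def donors(self) -> list[str]:
        return list(self.values.index.get_level_values("donor").unique())

    @property
    def networks(self) -> list[str]:
        return list(self.values.index.get_level_values("network").unique())

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format table with columns donor, network, gene, value."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["donor", "network", "gene", "value"]
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "NetworkExpression":
        missing = {"donor", "network", "gene", "value"} - set(long.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        wide = long.pivot_table(
            index=["donor", "network"], columns="gene", values="value", aggfunc="mean"
        )
        wide.index.names = ["donor", "network"]
        wide.columns.name = None
        counts = (~wide.isna()).any(axis=1).groupby(level=[0, 1]).sum().unstack(fill_value=0)
        return cls(wide, counts)


def aggregate_to_networks(
    matrix: ExpressionMatrix, assignments: pd.DataFrame, manifest: pd.DataFrame
) -> NetworkExpression:
    """Average samples within parcels, then parcel means within networks.

    The two-stage average weights parcels equally regardless of how many
    samples each contains, so a heavily sampled parcel does not dominate its
    network's value.
    """
    if matrix.value_scale not in (ValueScale.LOG2, ValueScale.LOG2_MEAN_NORMALIZED):
        raise ValueError("aggregate_to_networks requires log2 or log2_mean_normalized values")
    info = assignments.merge(
        manifest[["sample_id", "donor_id"]], on="sample_id", how="left", suffixes=("", "_m")
    )
    if "donor_id" not in info.columns or info["donor_id"].isna().any():
        raise ValueError("assignments reference samples missing from the manifest")
    info = info.dropna(subset=["network"])
    info = info[info["sample_id"].isin(matrix.sample_ids)]
    if info.empty:
        raise ValueError("no assigned samples overlap the expression matrix")
    samples_by_gene = matrix.values.T  # samples x genes
    joined = samples_by_gene.loc[info["sample_id"]]
    joined.index = pd.MultiIndex.from_arrays(
        [info["donor_id"], info["parcel"], info["network"]], names=["donor", "parcel", "network"]
    )
    parcel_means = joined.groupby(level=["donor", "parcel", "network"]).mean()
    network_means = parcel_means.groupby(level=["donor", "network"]).mean()
    parcel_counts = (
        parcel_means.reset_index()
        .groupby(["donor", "network"])
        .size()
        .unstack(fill_value=0)
    )
    return NetworkExpression(network_means, parcel_counts)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance prior
# ---------------------------------------------------------------------------


@dataclass
class VariancePrior:
    """Hyperparameters of the scaled-inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom, may be +inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (or +inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")

    def moderate(self, s_sq: np.ndarray, df: np.ndarray) -> np.ndarray:
        """Posterior-mean shrunken variances s~^2."""
        s_sq = np.asarray(s_sq, dtype=float)
        df = np.asarray(df, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s_sq, self.s0_sq)
        return (self.d0 * self.s0_sq + df * s_sq) / (self.d0 + df)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires positive input")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(residual_vars, residual_df) -> VariancePrior:
    """Fit (d0, s0^2) by method of moments on log sample variances.

    Under the scaled-inverse-chi-square model, e_g = log s_g^2
    - digamma(d_g/2) + log(d_g/2) has mean log s0^2 - digamma(d0/2)
    + log(d0/2) and excess variance trigamma(d0/2) beyond the sampling term
    trigamma(d_g/2). If the moment estimate leaves no excess variance, the
    prior is degenerate: d0 = +inf with s0^2 the mean sample variance.
    """
    s2 = np.asarray(residual_vars, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if not ok.any():
        raise ValueError("no positive residual variances with df >= 1")
    if ok.sum() < 2:
        raise ValueError(
            "variance prior needs >= 2 genes; fit without moderation instead"
        )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("estimate_variance_prior: dropped %d degenerate genes", n_dropped)
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return VariancePrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Donor blocking
# ---------------------------------------------------------------------------


@dataclass
class BlockingSpec:
    """How repeated observations from the same donor are handled."""

    mode: str = "consensus_correlation"
    consensus_rho: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "donor_fixed", "consensus_correlation"):
            raise ValueError(f"unknown blocking mode: {self.mode!r}")
        if self.consensus_rho is not None and not (-1 < self.consensus_rho < 1):
            raise ValueError("consensus_rho must lie in (-1, 1)")


def estimate_consensus_correlation(
    values: pd.DataFrame | np.ndarray,
    donors,
    design: np.ndarray | None = None,
    cap: float = 0.99,
    trim: float = 0.1,
) -> float:
    """Pooled intra-donor correlation of residuals across genes.

    Per gene, residuals from the supplied design (default: intercept only) are
    scored with the one-way ANOVA intraclass correlation over donor groups.
    The per-gene ICCs are capped at +-``cap``, Fisher-z transformed, and the
    10%-trimmed mean is transformed back to give a single consensus value.
    """
    Y = np.asarray(values, dtype=float)
    donors = np.asarray(donors)
    uniq, inv = np.unique(donors, return_inverse=True)
    counts = np.bincount(inv)
    if len(uniq) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("consensus correlation needs >= 2 donors with >= 2 observations each")
    n_obs = Y.shape[0]
    if design is None:
        design = np.ones((n_obs, 1))
    X = np.asarray(design, dtype=float)
    beta, *_ = np.linalg.lstsq(X, np.nan_to_num(Y), rcond=None)
    R = Y - X @ beta  # NaNs propagate through Y
    complete = ~np.isnan(R).any(axis=0)
    if not complete.any():
        raise ValueError("no genes with complete observations")
    R = R[:, complete]
    a = len(uniq)
    group_sum = np.zeros((a, R.shape[1]))
    np.add.at(group_sum, inv, R)
    group_mean = group_sum / counts[:, None]
    grand_mean = R.mean(axis=0)
    ssb = (counts[:, None] * (group_mean - grand_mean) ** 2).sum(axis=0)
    ssw = ((R - group_mean[inv]) ** 2).sum(axis=0)
    msb = ssb / (a - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        msw = ssw / max(n_obs - a, 1)
        k0 = (n_obs - (counts**2).sum() / n_obs) / (a - 1)
        icc = (msb - msw) / (msb + (k0 - 1) * msw)
    icc = np.clip(np.nan_to_num(icc, nan=0.0), -cap, cap)
    rho = float(np.tanh(stats.trim_mean(np.arctanh(icc), trim)))
    return float(np.clip(rho, -cap, cap))


def _whiten_blocks(X: np.ndarray, Y: np.ndarray, donor_codes: np.ndarray, rho: float):
    """Whiten rows under a compound-symmetric within-donor correlation."""
    Xw = np.empty_like(X)
    Yw = np.empty_like(Y)
    for code in np.unique(donor_codes):
        idx = np.where(donor_codes == code)[0]
        m = len(idx)
        sigma = np.full((m, m), rho) + (1.0 - rho) * np.eye(m)
        L = np.linalg.cholesky(sigma)
        Xw[idx] = np.linalg.solve(L, X[idx])
        Yw[idx] = np.linalg.solve(L, Y[idx])
    return Xw, Yw


def _ols_stats(X: np.ndarray, Y: np.ndarray, coef_index: int):
    """Vectorized per-gene OLS: coefficient, residual variance, df, avg."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient (collinear covariates?)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    v = float(xtx_inv[coef_index, coef_index])
    return beta[coef_index], s2, float(df), v


def fit_network_ovr(
    nexpr: NetworkExpression,
    target: str,
    blocking: BlockingSpec | None = None,
    covariates: pd.DataFrame | None = None,
    d0: float | None = None,
    trend: bool = False,
) -> pd.DataFrame:
    """One-vs-rest moderated differential expression for one target network.

    Fits, per gene, a linear model of the donor x network means on an
    intercept plus a target-network indicator (plus optional donor-level
    covariates such as age and sex), with donor blocking per ``blocking``.
    Residual variances are moderated with :func:`estimate_variance_prior`
    (pass ``d0=0`` to disable moderation or ``d0=numpy.inf`` to pool fully;
    ``trend=True`` replaces the constant prior variance with a LOWESS trend of
    log s_g^2 on average expression, appropriate for RNA-seq). Returns a table
    with columns gene, network, log2FC, avg_expr, t, df, p, q.
    """
    blocking = blocking or BlockingSpec()
    values = nexpr.values
    networks = values.index.get_level_values("network").to_numpy()
    donors = values.index.get_level_values("donor").to_numpy()
    if target not in set(networks):
        raise ValueError(f"target network {target!r} absent from the data")
    if len(set(networks)) < 2:
        raise ValueError("need observations from >= 2 networks")
    Y = values.to_numpy(dtype=float)
    n_obs, n_genes = Y.shape
    indicator = (networks == target).astype(float)

    cols = [np.ones(n_obs), indicator]
    if covariates is not None:
        cov = covariates.reindex(pd.Index(donors))
        if cov.isna().any().any():
            raise ValueError("covariates missing for some donors")
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))

    mode = blocking.mode
    uniq_donors, donor_codes = np.unique(donors, return_inverse=True)
    if mode == "consensus_correlation" and len(uniq_donors) < 2:
        logger.warning("single donor: falling back to blocking mode 'none'")
        mode = "none"

    if mode == "donor_fixed":
        for d in uniq_donors[1:]:
            cols.append((donors == d).astype(float))
    X = np.column_stack(cols)

    rho = None
    if mode == "consensus_correlation":
        rho = blocking.consensus_rho
        if rho is None:
            # residuals taken about the saturated network-means design so the
            # ICC reflects donor structure, not network structure
            net_design = np.column_stack(
                [(networks == n).astype(float) for n in np.unique(networks)]
            )
            rho = estimate_consensus_correlation(Y, donors, design=net_design)
            logger.info("estimated consensus intra-donor correlation: %.3f", rho)
        Xf, Yf = _whiten_blocks(X, Y, donor_codes, rho)
    else:
        Xf, Yf = X, Y

    complete = ~np.isnan(Yf).any(axis=0)
    coef = np.full(n_genes, np.nan)
    s2 = np.full(n_genes, np.nan)
    dfs = np.full(n_genes, np.nan)
    vs = np.full(n_genes, np.nan)
    if complete.any():
        c, s, d, v = _ols_stats(Xf, Yf[:, complete], coef_index=1)
        coef[complete], s2[complete], dfs[complete], vs[complete] = c, s, d, v
    for j in np.where(~complete)[0]:
        rows = ~np.isnan(Yf[:, j])
        if rows.sum() <= X.shape[1]:
            continue
        Xj = Xf[rows]
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            continue
        c, s, d, v = _ols_stats(Xj, Yf[rows, j][:, None], coef_index=1)
        coef[j], s2[j], dfs[j], vs[j] = c[0], s[0], d, v

    avg_expr = np.nanmean(Y, axis=0)

    usable = np.isfinite(s2) & (dfs >= 1)
    if d0 is not None and d0 == 0:
        s2_mod = s2
        df_total = dfs
    else:
        if trend:
            prior_d0, s0_per_gene = _trended_prior(s2[usable], dfs[usable], avg_expr[usable])
            if d0 is not None:
                prior_d0 = d0
            s0_sq = np.full(n_genes, np.nan)
            s0_sq[usable] = s0_per_gene
            if np.isinf(prior_d0):
                s2_mod = s0_sq
            else:
                s2_mod = (prior_d0 * s0_sq + dfs * s2) / (prior_d0 + dfs)
            df_total = dfs + prior_d0
        else:
            if d0 is not None and np.isinf(d0):
                prior = VariancePrior(d0=np.inf, s0_sq=float(np.nanmean(s2[usable])))
            elif d0 is not None:
                prior_fit = estimate_variance_prior(s2[usable], dfs[usable])
                prior = VariancePrior(d0=d0, s0_sq=prior_fit.s0_sq)
            else:
                prior = estimate_variance_prior(s2[usable], dfs[usable])
            s2_mod = prior.moderate(s2, dfs)
            df_total = dfs + prior.d0

    # numerically-zero contrasts (flat genes) must give t = 0, not 0/0 jitter
    scale = np.maximum(np.nanmax(np.abs(Y), axis=0), 1.0)
    flat = np.abs(coef) <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(s2_mod * vs)
    t = np.where(flat, 0.0, t)
    t = np.where(np.isfinite(t), t, np.where(coef == 0, 0.0, np.nan))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(p), p, np.nan)
    q = np.full(n_genes, np.nan)
    finite_p = np.isfinite(p)
    if finite_p.any():
        q[finite_p] = bh_adjust(p[finite_p])
    out = pd.DataFrame(
        {
            "gene": values.columns,
            "network": target,
            "log2FC": coef,
            "avg_expr": avg_expr,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
        }
    )
    return out


def _trended_prior(s2: np.ndarray, dfs: np.ndarray, avg_expr: np.ndarray):
    """Mean-variance trend prior: LOWESS of log s^2 on average expression."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    z = np.log(np.maximum(s2, 1e-300))
    fit = lowess(z, avg_expr, frac=0.5, return_sorted=False)
    resid_var = float(np.var(z - fit, ddof=1)) - float(np.mean(polygamma(1, dfs / 2.0)))
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
    else:
        d0 = np.inf
    s0_per_gene = np.exp(fit)
    return d0, s0_per_gene


# ---------------------------------------------------------------------------
# Multiple testing and gene-set extraction
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def positive_de_set(results: pd.DataFrame, q_max: float = 0.01) -> set[str]:
    """Genes positively biased toward the target network: q <= q_max, log2FC > 0."""
    sel = (results["q"] <= q_max) & (results["log2FC"] > 0)
    return set(results.loc[sel, "gene"])


# ---------------------------------------------------------------------------
# Within- vs between-network expression contrast
# ---------------------------------------------------------------------------


@dataclass
class WithinBetweenResult:
    F: float
    df: tuple[int, int]
    p: float
    within_mean: float
    within_se: float
    between_mean: float
    between_se: float
    per_donor: pd.DataFrame


def within_between_contrast(
    nexpr: NetworkExpression, gene_set, target_network: str
) -> WithinBetweenResult:
    """Paired contrast of gene-set expression inside vs outside a network.

    Per donor, the mean expression of ``gene_set`` in the target network
    (within) is compared with the average of the set's per-network means over
    the remaining networks (between). The test is the paired t across donors,
    reported as F = t^2 with df (1, D-1).
    """
    genes = [g for g in gene_set if g in nexpr.values.columns]
    if not genes:
        raise ValueError("gene set is empty or disjoint from the expression matrix")
    set_means = nexpr.values[genes].mean(axis=1)  # (donor, network) -> set mean
    rows = []
    for donor in nexpr.donors:
        donor_means = set_means.loc[donor]
        if target_network not in donor_means.index:
            continue
        others = donor_means.drop(target_network).dropna()
        if others.empty or pd.isna(donor_means[target_network]):
            continue
        rows.append(
            {
                "donor": donor,
                "within": float(donor_means[target_network]),
                "between": float(others.mean()),
            }
        )
    per_donor = pd.DataFrame(rows)
    if len(per_donor) < 2:
        raise ValueError("need >= 2 donors with both within and between values")
    diffs = per_donor["within"] - per_donor["between"]
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if diffs.mean() == 0 else np.inf
    else:
        t_stat = float(diffs.mean() / (sd / np.sqrt(n)))
    F = t_stat**2
    p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
    return WithinBetweenResult(
        F=float(F),
        df=(1, n - 1),
        p=p,
        within_mean=float(per_donor["within"].mean()),
        within_se=float(per_donor["within"].std(ddof=1) / np.sqrt(n)),
        between_mean=float(per_donor["between"].mean()),
        between_se=float(per_donor["between"].std(ddof=1) / np.sqrt(n)),
        per_donor=per_donor,
    )
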