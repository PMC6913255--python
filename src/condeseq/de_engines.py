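"""Three per-contrast differential-expression engines with one design convention.

The engines are principled native implementations of the three model families
that dominate bulk RNA-seq practice:

``nb_eb_lrt``
    NB GLM with tagwise dispersions shrunk by weighted-likelihood empirical
    Bayes toward an abundance trend, likelihood-ratio test on the group
    coefficient (the edgeR-style model family).  TMM normalisation.
``nb_wald``
    NB GLM with gene-wise dispersion MLEs shrunk log-normally toward a
    parametric trend a0 + a1/mu, Wald test on the group coefficient (the
    DESeq2-style family).  Median-of-ratios size factors.  Outlier-based
    p-value masking and independent filtering are deliberately disabled so
    every gene carries a comparable adjusted p-value for ranking.
``precision_weights``
    log2-CPM modelled by weighted least squares with inverse mean-variance
    trend precision weights and an empirical-Bayes moderated t-statistic
    (the voom/limma-style family).  TMM normalisation.

All engines share the design-matrix convention (intercept, group indicator
for group_b, optional pairing blocks, optional unwanted-variation covariates)
so pairing and RUV factors enter each model identically, and all report
logFC = log2(group_b / group_a), a common AveExpr (mean log2-CPM), raw and
Benjamini-Hochberg adjusted p-values, and the significance rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import digamma, polygamma
from scipy.stats import chi2, norm as normal_dist, rankdata, t as t_dist

from . import _glm
from .errors import DataError, DesignError, EngineError, EstimationError
from .experiment_io import ContrastPair, CountExperiment, subset_for_pair
from .normalization import NormFactors, compute_factors, cpm_matrix, tmm_factors

logger = logging.getLogger(__name__)

LOG2E = np.log2(np.e)

ENGINE_ROLES = {
    "nb_eb_lrt": "edger",
    "nb_wald": "deseq",
    "precision_weights": "voom",
}
DEFAULT_NORM = {
    "nb_eb_lrt": "tmm",
    "nb_wald": "median_ratio",
    "precision_weights": "tmm",
}

DISPERSION_PRIOR_DF = 10.0  # weighted-likelihood shrinkage strength (nb_eb_lrt)


# --------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Model matrix shared by all engines for one contrast.

    Columns: intercept, the tested group indicator (1 for samples of
    group_b), optional pairing-block indicators and optional RUV covariates.
    """

    matrix: np.ndarray
    columns: list[str]
    coef: str = "group"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise DesignError("design matrix shape does not match column names")
        if self.coef not in self.columns:
            raise DesignError(f"tested coefficient {self.coef!r} not in design")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def coef_index(self) -> int:
        return self.columns.index(self.coef)

    @property
    def residual_df(self) -> int:
        return self.n_samples - self.n_params

    def reduced(self) -> "DesignMatrix":
        """The null design with the tested coefficient removed."""
        keep = [i for i, c in enumerate(self.columns) if c != self.coef]
        reduced = DesignMatrix.__new__(DesignMatrix)
        reduced.matrix = self.matrix[:, keep]
        reduced.columns = [self.columns[i] for i in keep]
        reduced.coef = self.coef  # retained for bookkeeping, not present
        return reduced


def build_design(sample_meta: pd.DataFrame, pair: ContrastPair) -> DesignMatrix:
    """Intercept + group indicator (+ pairing blocks) for one contrast.

    ``sample_meta`` must contain exactly the samples of the two contrast
    groups, in count-matrix column order.
    """
    groups = sample_meta["group"].astype(str)
    extra = sorted(set(groups) - {pair.group_a, pair.group_b})
    if extra:
        raise DesignError(f"sample_meta contains off-contrast groups: {extra}")
    cols = [np.ones(len(sample_meta)), (groups == pair.group_b).to_numpy(float)]
    names = ["Intercept", "group"]
    if "pairs" in sample_meta.columns and sample_meta["pairs"].notna().any():
        if sample_meta["pairs"].isna().any():
            raise DesignError("paired design requires a pair ID for every sample")
        levels = sorted(sample_meta["pairs"].astype(str).unique())
        for lev in levels[1:]:
            cols.append((sample_meta["pairs"].astype(str) == lev).to_numpy(float))
            names.append(f"pair_{lev}")
    return DesignMatrix(matrix=np.column_stack(cols), columns=names)


# --------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment; NA propagates, output <= 1."""
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    vals = p[finite]
    n = vals.size
    if n == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(n)
    result[order] = np.minimum(adjusted, 1.0)
    out[finite] = result
    return out


# --------------------------------------------------------------------------
# engine result container


@dataclass
class EngineResult:
    """One engine's per-gene output for one contrast.

    ``table`` is indexed by gene ID with columns logFC (log2), AveExpr
    (mean log2-CPM), p_raw, p_adj (BH) and rank (1 = most significant,
    ties averaged, NA for untestable genes).
    """

    engine: str
    pair: ContrastPair
    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    @property
    def role(self) -> str:
        return ENGINE_ROLES[self.engine]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="ID")


def _finalize(engine, pair, gene_ids, logfc, ave_expr, p_raw, extras) -> EngineResult:
    p_adj = bh_adjust(p_raw)
    rank = rankdata(p_raw, method="average", nan_policy="omit")
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": ave_expr,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "rank": rank,
        },
        index=pd.Index(gene_ids, name="ID"),
    )
    return EngineResult(engine=engine, pair=pair, table=table, extras=extras)


def _prepare(exp, pair, design, norm, default_method):
    """Common engine entry: subset samples, build design, compute factors."""
    sub = subset_for_pair(exp, pair)
    if design is None:
        design = build_design(sub.sample_meta, pair)
    if design.n_samples != len(sub.sample_names):
        raise DesignError("design rows do not match contrast samples")
    if norm is None:
        norm = compute_factors(sub.counts, default_method)
    y = sub.counts.to_numpy(dtype=float)
    # AveExpr uses one formula for every engine (mean log2-CPM under TMM
    # effective library sizes) so the merged average combines commensurate
    # quantities.
    tmm = norm if norm.method == "tmm" else tmm_factors(sub.counts)
    ave_expr = cpm_matrix(y, tmm, log=True).mean(axis=1)
    return sub, design, norm, y, ave_expr


# --------------------------------------------------------------------------
# NB-EB-LRT engine (edgeR-style)


def _moving_average_by_order(values: np.ndarray, order: np.ndarray, width: int):
    """Moving average of ``values`` taken along a given ordering."""
    g = values.shape[0]
    if g <= width:
        return np.full(g, values.mean())
    sorted_vals = values[order]
    kernel = np.ones(width) / width
    pad_lo = np.full(width // 2, sorted_vals[: width // 2].mean())
    pad_hi = np.full(width - 1 - width // 2, sorted_vals[-(width // 2) :].mean())
    padded = np.concatenate([pad_lo, sorted_vals, pad_hi])
    smoothed = np.convolve(padded, kernel, mode="valid")
    out = np.empty(g)
    out[order] = smoothed
    return out


def estimate_tagwise_dispersion(
    counts: np.ndarray,
    design: DesignMatrix,
    offsets: np.ndarray,
    ave_expr: np.ndarray | None = None,
    prior_df: float = DISPERSION_PRIOR_DF,
    grid_size: int = 19,
):
    """Common + tagwise NB dispersions by Cox-Reid adjusted profile likelihood.

    The common dispersion maximises the summed adjusted profile likelihood
    (APL) across genes.  Tagwise values maximise the weighted likelihood
    APL_g + (prior_df / residual df) * S_g, where S_g is the APL smoothed
    over genes ordered by abundance (moving average), shrinking each gene
    toward the local abundance trend with prior_df worth of shared evidence.

    Returns (tagwise dispersions, common dispersion).
    """
    y = np.asarray(counts, dtype=float)
    G = y.shape[0]
    if design.residual_df < 1:
        raise EstimationError("dispersion estimation needs >=1 residual df")
    if not (y.sum(axis=1) > 0).all():
        raise EstimationError("all-zero genes must be excluded before estimation")
    X = design.matrix

    coarse = np.exp(np.linspace(np.log(1e-6), np.log(_glm.MAX_PHI), 15))
    apl_c = _glm.apl_grid(y, X, offsets, coarse)
    common = float(
        np.exp(_glm.interp_argmax(np.log(coarse), apl_c.sum(axis=0)[None, :]))[0]
    )
    common = float(np.clip(common, _glm.MIN_PHI, _glm.MAX_PHI))
    if G == 1:
        return np.array([common]), common

    span = np.log(2.0) * 9.0
    log_grid = np.linspace(np.log(common) - span, np.log(common) + span, grid_size)
    log_grid = np.clip(log_grid, np.log(_glm.MIN_PHI), np.log(_glm.MAX_PHI))
    apl = _glm.apl_grid(y, X, offsets, np.exp(log_grid))

    if ave_expr is None:
        lib = y.sum(axis=0)
        ave_expr = np.log2((y + 0.5) / (lib + 1.0) * 1e6).mean(axis=1)
    order = np.argsort(ave_expr, kind="mergesort")
    width = max(10, int(round(0.1 * G)))
    shared = np.column_stack(
        [_moving_average_by_order(apl[:, k], order, width) for k in range(apl.shape[1])]
    )
    prior_n = prior_df / design.residual_df
    score = apl + prior_n * shared
    tagwise = np.exp(_glm.interp_argmax(log_grid, score))
    return np.clip(tagwise, _glm.MIN_PHI, _glm.MAX_PHI), common


def fit_nb_eb_lrt(
    exp: CountExperiment,
    pair: ContrastPair,
    design: DesignMatrix | None = None,
    norm: NormFactors | None = None,
    prior_df: float = DISPERSION_PRIOR_DF,
) -> EngineResult:
    """NB GLM + empirical-Bayes tagwise dispersion + likelihood-ratio test."""
    sub, design, norm, y, ave_expr = _prepare(
        exp, pair, design, norm, DEFAULT_NORM["nb_eb_lrt"]
    )
    if design.residual_df < 1:
        raise EngineError("nb_eb_lrt requires >=1 residual df")
    offsets = np.log(norm.effective_lib_sizes)
    G = y.shape[0]
    logfc = np.zeros(G)
    p_raw = np.full(G, np.nan)
    tested = y.sum(axis=1) > 0

    extras: dict = {}
    if tested.any():
        yt = y[tested]
        tagwise, common = estimate_tagwise_dispersion(
            yt, design, offsets, ave_expr[tested], prior_df=prior_df
        )
        full = _glm.fit_nb_glm(yt, design.matrix, offsets, tagwise)
        red = _glm.fit_nb_glm(yt, design.reduced().matrix, offsets, tagwise)
        lrt = np.maximum(red.deviance - full.deviance, 0.0)
        p = chi2.sf(lrt, df=1)
        bad = ~(full.converged & red.converged)
        if bad.any():
            logger.warning("nb_eb_lrt: %d gene(s) failed to converge", int(bad.sum()))
            p[bad] = np.nan
        logfc[tested] = full.beta[:, design.coef_index] * LOG2E
        p_raw[tested] = p
        disp = np.full(G, np.nan)
        disp[tested] = tagwise
        extras = {"dispersion": disp, "common_dispersion": common, "norm": norm}
    return _finalize("nb_eb_lrt", pair, sub.gene_ids, logfc, ave_expr, p_raw, extras)


# --------------------------------------------------------------------------
# NB-Wald engine (DESeq2-style)


def _fit_dispersion_trend(disp: np.ndarray, base_mean: np.ndarray):
    """Parametric trend phi(mu) = a0 + a1/mu by iterative gamma regression.

    Genes whose dispersion-to-trend ratio leaves [1e-4, 15] are dropped and
    the fit repeated until the coefficients stabilise.  Returns (a0, a1) or
    None when no valid fit exists (caller falls back to the median).
    """
    usable = (disp > 1e-6) & (base_mean > 0)
    if usable.sum() < 10:
        return None
    d = disp[usable]
    m = base_mean[usable]
    coefs = None
    for _ in range(10):
        exog = np.column_stack([np.ones(d.size), 1.0 / m])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    d, exog, family=sm.families.Gamma(link=sm.families.links.Identity())
                )
                start = np.maximum(np.linalg.lstsq(exog, d, rcond=None)[0], 1e-6)
                res = model.fit(start_params=start, maxiter=100)
        except Exception:
            return None
        new = res.params
        if new[0] <= 0 or new[1] < 0:
            return None
        if coefs is not None and np.allclose(new, coefs, rtol=1e-4):
            coefs = new
            break
        coefs = new
        ratio = d / (coefs[0] + coefs[1] / m)
        keep = (ratio > 1e-4) & (ratio < 15)
        if keep.all() or keep.sum() < 10:
            break
        d, m = d[keep], m[keep]
    return tuple(coefs) if coefs is not None else None


def fit_nb_wald(
    exp: CountExperiment,
    pair: ContrastPair,
    design: DesignMatrix | None = None,
    norm: NormFactors | None = None,
) -> EngineResult:
    """NB GLM with trend-shrunken MAP dispersions and a Wald test.

    No outlier-based p-value masking and no independent filtering: every
    testable gene receives raw and adjusted p-values so that significance
    ranks are comparable across engines.
    """
    sub, design, norm, y, ave_expr = _prepare(
        exp, pair, design, norm, DEFAULT_NORM["nb_wald"]
    )
    if design.residual_df < 1:
        raise EngineError("nb_wald requires >=1 residual df")
    sf = norm.factors
    offsets = np.log(sf)
    G, n = y.shape
    logfc = np.zeros(G)
    p_raw = np.full(G, np.nan)
    tested = y.sum(axis=1) > 0
    extras: dict = {}
    if tested.any():
        yt = y[tested]
        X = design.matrix
        base_mean = (yt / sf).mean(axis=1)

        log_grid = np.linspace(np.log(1e-7), np.log(_glm.MAX_PHI), 25)
        apl = _glm.apl_grid(yt, X, offsets, np.exp(log_grid))
        disp_mle = np.exp(_glm.interp_argmax(log_grid, apl))

        trend_coef = _fit_dispersion_trend(disp_mle, base_mean)
        if trend_coef is None:
            warnings.warn(
                "dispersion trend fit failed; falling back to the median "
                "gene-wise dispersion",
                RuntimeWarning,
                stacklevel=2,
            )
            trend = np.full(yt.shape[0], max(np.median(disp_mle), 1e-6))
        else:
            a0, a1 = trend_coef
            trend = a0 + a1 / np.maximum(base_mean, 1e-8)

        informative = disp_mle > 1e-6
        if informative.sum() >= 3:
            lr = np.log(disp_mle[informative]) - np.log(trend[informative])
            mad = np.median(np.abs(lr - np.median(lr)))
            s2_lr = (1.4826 * mad) ** 2
        else:
            s2_lr = 0.0
        sampling_var = float(polygamma(1, max(design.residual_df, 1) / 2.0))
        sigma2_prior = max(s2_lr - sampling_var, 0.25)

        penalty = (log_grid[None, :] - np.log(trend)[:, None]) ** 2 / (
            2.0 * sigma2_prior
        )
        disp_map = np.exp(_glm.interp_argmax(log_grid, apl - penalty))
        disp_map = np.clip(disp_map, _glm.MIN_PHI, _glm.MAX_PHI)

        final = _glm.fit_nb_glm(yt, X, offsets, disp_map)
        cov = np.linalg.inv(final.xtwx)
        idx = design.coef_index
        se = np.sqrt(np.maximum(cov[:, idx, idx], 1e-300))
        wald = final.beta[:, idx] / se
        p = 2.0 * normal_dist.sf(np.abs(wald))
        bad = ~final.converged
        if bad.any():
            logger.warning("nb_wald: %d gene(s) failed to converge", int(bad.sum()))
            p[bad] = np.nan
        logfc[tested] = final.beta[:, idx] * LOG2E
        p_raw[tested] = p
        disp_full = np.full(G, np.nan)
        disp_full[tested] = disp_map
        extras = {
            "dispersion": disp_full,
            "trend_coef": trend_coef,
            "sigma2_prior": sigma2_prior,
            "norm": norm,
        }
    return _finalize("nb_wald", pair, sub.gene_ids, logfc, ave_expr, p_raw, extras)


# --------------------------------------------------------------------------
# precision-weights engine (voom/limma-style)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_f_dist(s2: np.ndarray, df1: float):
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Returns (prior df, prior variance); prior df is inf when the observed
    log-variance spread is no wider than the sampling spread.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * trigamma_inverse(evar)
        s20 = np.exp(emean + digamma(df2 / 2.0) - np.log(df2 / 2.0))
    else:
        df2 = np.inf
        s20 = np.exp(emean)
    return df2, float(s20)


def fit_precision_weights(
    exp: CountExperiment,
    pair: ContrastPair,
    design: DesignMatrix | None = None,
    norm: NormFactors | None = None,
    prior_df: float | None = None,
    lowess_frac: float = 0.5,
) -> EngineResult:
    """Precision-weighted linear model on log2-CPM with a moderated t-test.

    The gene-wise sqrt-residual-SD versus mean log2-count relationship is
    smoothed by lowess; its inverse fourth power at each fitted log-count
    supplies the observation weights.  Residual variances are then shrunk
    toward a moment-fitted scaled inverse-chi-square prior and the group
    coefficient tested with a t-statistic on residual + prior df.

    ``prior_df`` overrides the fitted prior df (0 recovers the ordinary
    weighted t-statistic; inf pools all genes to one prior variance).
    """
    sub, design, norm, y, ave_expr = _prepare(
        exp, pair, design, norm, DEFAULT_NORM["precision_weights"]
    )
    df_res = design.residual_df
    if df_res < 2:
        raise EngineError(
            "precision_weights requires >=2 residual df for variance moderation"
        )
    X = design.matrix
    G, n = y.shape
    p = X.shape[1]
    eff = norm.effective_lib_sizes
    logcpm = np.log2((y + 0.5) / (eff + 1.0) * 1e6)

    pinv = np.linalg.pinv(X)
    beta1 = logcpm @ pinv.T
    fitted = beta1 @ X.T
    resid = logcpm - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_res)

    # mean-variance trend on the log2-count scale
    mean_log_count = ave_expr + np.log2(np.exp(np.mean(np.log(eff + 1.0)))) - np.log2(1e6)
    sqrt_sd = np.sqrt(np.maximum(sigma, 1e-12))
    trend_src = y.sum(axis=1) > 0
    if trend_src.sum() >= 10:
        lo = sm.nonparametric.lowess(
            sqrt_sd[trend_src],
            mean_log_count[trend_src],
            frac=lowess_frac,
            it=3,
            delta=0.01 * np.ptp(mean_log_count[trend_src]),
        )
        lx, ly = lo[:, 0], lo[:, 1]
    else:
        lx = np.array([mean_log_count.min(), mean_log_count.max()])
        ly = np.full(2, sqrt_sd.mean())
    fitted_log_count = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    trend_sqrt_sd = np.interp(fitted_log_count, lx, ly)
    weights = 1.0 / np.clip(trend_sqrt_sd, 1e-6, None) ** 4

    xtwx = np.einsum("gn,ni,nj->gij", weights, X, X, optimize=True)
    xtwz = np.einsum("gn,ni->gi", weights * logcpm, X, optimize=True)
    beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
    resid_w = logcpm - beta @ X.T
    s2 = (weights * resid_w**2).sum(axis=1) / df_res
    cov = np.linalg.inv(xtwx)
    idx = design.coef_index
    unscaled_var = cov[:, idx, idx]

    df_prior, s2_prior = fit_f_dist(s2, df_res)
    if prior_df is not None:
        df_prior = float(prior_df)
        if np.isinf(df_prior):
            s2_prior = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-12)))))
    if df_prior == 0:
        s2_post = s2
    elif np.isinf(df_prior):
        s2_post = np.full(G, s2_prior)
    else:
        s2_post = (df_res * s2 + df_prior * s2_prior) / (df_res + df_prior)

    tstat = beta[:, idx] / np.sqrt(np.maximum(unscaled_var * s2_post, 1e-300))
    df_total = df_res + df_prior
    if np.isinf(df_total):
        p_raw = 2.0 * normal_dist.sf(np.abs(tstat))
    else:
        p_raw = 2.0 * t_dist.sf(np.abs(tstat), df_total)

    logfc = beta[:, idx].copy()
    zero = y.sum(axis=1) == 0
    logfc[zero] = 0.0
    p_raw = np.asarray(p_raw, dtype=float)
    p_raw[zero] = np.nan

    extras = {
        "t": tstat,
        "df_prior": df_prior,
        "s2_prior": s2_prior,
        "s2_post": s2_post,
        "weights_range": (float(weights.min()), float(weights.max())),
        "norm": norm,
    }
    return _finalize(
        "precision_weights", pair, sub.gene_ids, logfc, ave_expr, p_raw, extras
    )


ENGINES = {
    "nb_eb_lrt": fit_nb_eb_lrt,
    "nb_wald": fit_nb_wald,
    "precision_weights": fit_precision_weights,
}
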