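"""Library normalisation: TMM scale factors, median-of-ratios size factors, CPM.

Each DE engine uses its own default normalisation ("all_defaults"): the
NB-EB-LRT and precision-weights engines use trimmed-mean-of-M (TMM) scale
factors, the NB-Wald engine uses median-of-ratios size factors.  A single
method can also be forced across all engines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NormalizationError

TMM_TRIM_M = 0.30  # two-sided trim fraction on M-values
TMM_TRIM_A = 0.05  # two-sided trim fraction on A-values
LOG_CPM_PRIOR = 0.5


@dataclass
class NormFactors:
    """Per-sample scaling for one of {tmm, median_ratio, none}.

    For TMM, ``factors`` are scale factors with geometric mean 1 and the
    effective library size is library size x factor.  For median-of-ratios,
    ``factors`` are the size factors themselves; the effective library size
    used for CPM-scale quantities is size factor x geometric-mean library
    size, so CPMs stay on a per-million scale.
    """

    method: str
    factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if (self.factors <= 0).any():
            raise NormalizationError("normalisation factors must be positive")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        if self.method == "median_ratio":
            geo = np.exp(np.mean(np.log(self.lib_sizes)))
            return self.factors * geo
        return self.lib_sizes * self.factors


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        counts = counts.to_numpy()
    return np.asarray(counts, dtype=float)


def tmm_factors(counts, ref: int | None = None) -> NormFactors:
    """Trimmed mean of M-values scale factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile (lowest index on ties) unless ``ref``
    is given.  M-values are trimmed 30% each side, A-values 5% each side, and
    the surviving M-values are averaged with inverse delta-method variance
    weights.  Factors are rescaled to geometric mean 1, so sequencing depth
    is absorbed entirely by the library sizes.
    """
    y = _as_matrix(counts)
    if y.shape[1] < 2:
        raise NormalizationError("TMM requires >=2 samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = np.where(lib <= 0)[0].tolist()
        raise NormalizationError(f"all-zero sample column(s) at index {bad}")

    if ref is None:
        f75 = np.quantile(y, 0.75, axis=0) / lib
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(method="tmm", factors=factors, lib_sizes=lib)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """log2 TMM factor of ``obs`` against ``ref``."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 0.0
    p_obs, p_ref = obs[pos] / n_obs, ref[pos] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; weights are its reciprocal
    v = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])

    n = m.size
    if n == 0 or np.max(np.abs(m)) < 1e-10:
        return 0.0
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    lo_m, lo_a = np.floor(n * TMM_TRIM_M) + 1, np.floor(n * TMM_TRIM_A) + 1
    keep = (
        (rank_m >= lo_m)
        & (rank_m <= n + 1 - lo_m)
        & (rank_a >= lo_a)
        & (rank_a <= n + 1 - lo_a)
    )
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def median_ratio_size_factors(counts) -> NormFactors:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only genes with strictly positive counts in every sample enter the
    pseudo-reference; with none, filtering low-count genes first is advised.
    """
    y = _as_matrix(counts)
    positive = (y > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has positive counts in all samples; filter low-count "
            "genes before computing median-of-ratios size factors"
        )
    sub = y[positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return NormFactors(method="median_ratio", factors=factors, lib_sizes=y.sum(axis=0))


def no_normalization(counts) -> NormFactors:
    y = _as_matrix(counts)
    return NormFactors(
        method="none", factors=np.ones(y.shape[1]), lib_sizes=y.sum(axis=0)
    )


def compute_factors(counts, method: str) -> NormFactors:
    if method == "tmm":
        return tmm_factors(counts)
    if method == "median_ratio":
        return median_ratio_size_factors(counts)
    if method == "none":
        return no_normalization(counts)
    raise NormalizationError(f"unknown normalisation method {method!r}")


def cpm_matrix(
    counts, factors: NormFactors, log: bool = False, prior: float = LOG_CPM_PRIOR
) -> np.ndarray:
    """Counts per million effective library size.

    The log variant is log2((count + prior) / (effective libsize + 2 * prior)
    * 1e6) with prior 0.5 by default, matching the precision-weights engine's
    transform.
    """
    y = _as_matrix(counts)
    eff = factors.effective_lib_sizes
    if log:
        return np.log2((y + prior) / (eff + 2.0 * prior) * 1e6)
    return y / eff * 1e6


def write_factors(factors: NormFactors, path, sample_names=None) -> None:
    names = (
        list(sample_names)
        if sample_names is not None
        else [f"s{i}" for i in range(len(factors.factors))]
    )
    pd.DataFrame({"sample": names, "factor": factors.factors}).to_csv(
        path, sep="\t", index=False
    )
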