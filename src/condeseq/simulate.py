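"""Negative-binomial count simulation with a known differential-expression truth.

Per-gene NB parameters (mean at a reference depth, dispersion phi with
Var = mu + phi * mu^2) are estimated from any real count matrix, or taken
from the bundled synthetic parameter set.  A simulated two-group experiment
plants a configurable number of DE genes with known signed log2 fold
changes; everything downstream (engines, consensus, evaluation) can then be
scored against that truth.

Defaults reproduce the benchmark design used throughout this package:
10,000 genes, 500 DE (5%) split equally up/down, 3 or 5 replicates per
group, 10 simulation repeats.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, EstimationError
from .experiment_io import CountExperiment
from .normalization import median_ratio_size_factors

#: DE genes draw |log2FC| uniformly from this range (1.5x to 4x).
DEFAULT_LFC_RANGE = (0.585, 2.0)
#: Per-sample sequencing depths are log-normal around the reference depth.
DEFAULT_LIBSIZE_SIGMA = 0.15


@dataclass
class NBParams:
    """Per-gene NB parameters at a reference sequencing depth."""

    mean: np.ndarray
    dispersion: np.ndarray
    source_lib_size: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if self.mean.shape != self.dispersion.shape:
            raise ConfigError("mean and dispersion must have equal length")
        if (self.mean <= 0).any():
            raise ConfigError("NB means must be positive")
        if (self.dispersion < 0).any():
            raise ConfigError("NB dispersions must be non-negative")

    def __len__(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "dispersion": self.dispersion})


@dataclass
class SimConfig:
    """Simulation design.

    ``n_de`` of ``n_genes`` genes are DE, a fraction ``prop_up``
    up-regulated (count rounded up), the rest down.  ``replicates`` is per
    group.  |log2FC| of DE genes is uniform over ``lfc_range``.
    """

    n_genes: int = 10_000
    n_de: int = 500
    prop_up: float = 0.5
    replicates: int = 3
    n_sims: int = 10
    lfc_range: tuple[float, float] = DEFAULT_LFC_RANGE
    libsize_sigma: float = DEFAULT_LIBSIZE_SIGMA
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ConfigError("n_de cannot exceed n_genes")
        if not 0.0 <= self.prop_up <= 1.0:
            raise ConfigError("prop_up must lie in [0, 1]")
        if self.replicates < 2:
            raise ConfigError("at least 2 replicates per group are required")
        if self.lfc_range[0] < 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ConfigError("invalid lfc_range")


@dataclass
class SimulatedExperiment:
    """Simulated two-group experiment plus its per-gene truth table.

    ``truth`` is indexed like the counts with columns is_de, direction
    (up/down/none, relative to group B over group A) and true_log2fc.
    """

    experiment: CountExperiment
    truth: pd.DataFrame
    config: SimConfig = field(default=None)  # type: ignore[assignment]

    @property
    def de_genes(self) -> set:
        return set(self.truth.index[self.truth["is_de"]])


def estimate_nb_params(counts) -> NBParams:
    """Method-of-moments NB parameter estimation from a real count matrix.

    Counts are median-of-ratios normalised; per-gene dispersion is
    max(0, (s^2 - mu) / mu^2).  All-zero genes are excluded from the pool.
    Genes with positive variance whose moment estimate is zero or negative
    (under-dispersion, i.e. sampling noise) are floored to a lowess
    mean-dispersion trend; genes with zero sample variance keep dispersion 0.
    """
    counts = pd.DataFrame(counts)
    if counts.shape[1] < 2:
        raise EstimationError("parameter estimation requires >=2 samples")
    y = counts.to_numpy(dtype=float)
    expressed = y.sum(axis=1) > 0
    if not expressed.all():
        y = y[expressed]
    if y.shape[0] < 2:
        raise EstimationError("too few expressed genes for estimation")

    factors = median_ratio_size_factors(y)
    normed = y / factors.factors
    mu = normed.mean(axis=1)
    s2 = normed.var(axis=1, ddof=1)
    mom = (s2 - mu) / mu**2

    log_mu = np.log10(mu)
    if y.shape[0] >= 20 and np.ptp(log_mu) > 0:
        with np.errstate(invalid="ignore"):
            trend = sm.nonparametric.lowess(
                mom, log_mu, frac=0.4, it=2,
                delta=0.01 * np.ptp(log_mu), return_sorted=True,
            )
        trend_at = np.maximum(np.interp(log_mu, trend[:, 0], trend[:, 1]), 0.0)
    else:  # too few genes for a trend; fall back to the mean excess
        trend_at = np.full(y.shape[0], max(float(np.mean(mom)), 0.0))

    phi = np.maximum(mom, 0.0)
    noisy = (s2 > 0) & (mom <= 0)
    phi[noisy] = trend_at[noisy]
    return NBParams(
        mean=mu, dispersion=phi, source_lib_size=float(y.sum(axis=0).mean())
    )


def simulate_experiment(
    config: SimConfig, params: NBParams, seed: int | None = None
) -> SimulatedExperiment:
    """Draw a two-group NB experiment with planted DE, deterministic per seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_pool = len(params)

    replace = n_pool < config.n_genes
    pick = rng.choice(n_pool, size=config.n_genes, replace=replace)
    mean = params.mean[pick]
    phi = params.dispersion[pick]

    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    n_up = int(np.ceil(config.n_de * config.prop_up))
    lfc = np.zeros(config.n_genes)
    if config.n_de:
        magnitude = rng.uniform(*config.lfc_range, size=config.n_de)
        sign = np.ones(config.n_de)
        sign[n_up:] = -1.0
        lfc[de_idx] = sign * magnitude

    n_rep = config.replicates
    ref = params.source_lib_size
    depths = ref * np.exp(rng.normal(0.0, config.libsize_sigma, size=2 * n_rep))
    mu_b = mean * 2.0**lfc
    mu_matrix = np.empty((config.n_genes, 2 * n_rep))
    mu_matrix[:, :n_rep] = mean[:, None] * (depths[:n_rep] / ref)
    mu_matrix[:, n_rep:] = mu_b[:, None] * (depths[n_rep:] / ref)

    counts = np.empty_like(mu_matrix, dtype=np.int64)
    overdispersed = phi > 1e-10
    if overdispersed.any():
        r = 1.0 / phi[overdispersed, None]
        p = r / (r + mu_matrix[overdispersed])
        counts[overdispersed] = rng.negative_binomial(r, p)
    if (~overdispersed).any():
        counts[~overdispersed] = rng.poisson(mu_matrix[~overdispersed])

    gene_ids = [f"gene_{i + 1}" for i in range(config.n_genes)]
    sample_names = [f"A_{j + 1}" for j in range(n_rep)] + [
        f"B_{j + 1}" for j in range(n_rep)
    ]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_names)
    meta = pd.DataFrame(
        {"file": sample_names, "group": ["A"] * n_rep + ["B"] * n_rep},
        index=pd.Index(sample_names, name="sample"),
    )
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    truth = pd.DataFrame(
        {"is_de": lfc != 0.0, "direction": direction, "true_log2fc": lfc},
        index=pd.Index(gene_ids, name="ID"),
    )
    exp = CountExperiment(counts=counts_df, sample_meta=meta)
    return SimulatedExperiment(experiment=exp, truth=truth, config=config)


def apply_batch_effect(
    sim: SimulatedExperiment,
    factors: np.ndarray,
    gene_fraction: float = 0.3,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Inject a multiplicative per-sample batch effect into a simulation.

    A random ``gene_fraction`` of genes respond to the batch: their counts
    are re-drawn as Poisson around count * factor_j.  Restricting the effect
    to a gene subset keeps it distinct from a library-size change (which
    normalisation would absorb entirely), mimicking how real technical
    artefacts hit gene subsets.  This is the hook the unwanted-variation
    correction is tested against.
    """
    factors = np.asarray(factors, dtype=float)
    counts = sim.experiment.counts
    if factors.size != counts.shape[1]:
        raise ConfigError("one batch factor per sample is required")
    if not 0 < gene_fraction <= 1:
        raise ConfigError("gene_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_affected = int(round(gene_fraction * counts.shape[0]))
    affected = rng.choice(counts.shape[0], size=n_affected, replace=False)
    scaled = counts.to_numpy(dtype=float).copy()
    scaled[affected] = rng.poisson(scaled[affected] * factors[None, :])
    scaled = scaled.astype(np.int64)
    exp = CountExperiment(
        counts=pd.DataFrame(scaled, index=counts.index, columns=counts.columns),
        sample_meta=sim.experiment.sample_meta,
        annotations=sim.experiment.annotations,
    )
    return SimulatedExperiment(experiment=exp, truth=sim.truth, config=sim.config)


# --------------------------------------------------------------------------
# bundled parameter set

#: Version and frozen checksum of the bundled synthetic parameter set.
BUNDLED_PARAMS_VERSION = "1.0"
BUNDLED_PARAMS_SEED = 77003917
BUNDLED_PARAMS_SIZE = 12_000
BUNDLED_PARAMS_LIBSIZE = 8_000_000.0
BUNDLED_PARAMS_SHA256 = (
    "6ae2705419c6a7d572506befad9e23879f08ffafdef240b263274fae710b36eb"
)


def _generate_bundled_params() -> NBParams:
    """Deterministically generate the bundled synthetic parameter set.

    This is a synthetic stand-in for parameters estimated from a real bulk
    RNA-seq count matrix (kept generative rather than shipped as a table so
    the package stays plain text).  Expressed-gene means are log-normal with
    a heavy right tail, scaled to an 8M-read reference depth; dispersions
    follow the canonical decreasing mean-dispersion trend
    phi = phi0 + c / mu (asymptotic biological CV ~0.14, typical of
    genetically homogeneous model-organism replicates) with log-normal
    biological scatter.
    """
    rng = np.random.default_rng(BUNDLED_PARAMS_SEED)
    g = BUNDLED_PARAMS_SIZE
    rel = np.exp(rng.normal(1.0, 2.0, size=g))
    mean = rel * (BUNDLED_PARAMS_LIBSIZE / rel.sum())
    mean = np.maximum(mean, 0.2)
    trend = 0.02 + 2.5 / mean
    phi = trend * np.exp(rng.normal(0.0, 0.6, size=g))
    phi = np.clip(phi, 1e-4, 5.0)
    return NBParams(
        mean=mean, dispersion=phi, source_lib_size=BUNDLED_PARAMS_LIBSIZE
    )


def params_checksum(params: NBParams) -> str:
    """SHA-256 of the canonical TSV serialization of a parameter set."""
    buf = io.StringIO()
    buf.write(f"# version={BUNDLED_PARAMS_VERSION}\n")
    for m, d in zip(params.mean, params.dispersion):
        buf.write(f"{m:.6e}\t{d:.6e}\n")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def bundled_params(verify: bool = True) -> NBParams:
    """The bundled synthetic >=10,000-gene NB parameter set.

    Generated deterministically and, by default, verified against the frozen
    manifest checksum.
    """
    params = _generate_bundled_params()
    if verify:
        digest = params_checksum(params)
        if digest != BUNDLED_PARAMS_SHA256:
            raise EstimationError(
                "bundled parameter set failed its integrity check: "
                f"{digest} != {BUNDLED_PARAMS_SHA256}"
            )
    return params


def write_simulation(sim: SimulatedExperiment, outdir) -> dict:
    """Write counts, truth and the sample table as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "samples": outdir / "samples.tsv",
    }
    sim.experiment.counts.to_csv(paths["counts"], sep="\t", index_label="ID")
    sim.truth.to_csv(paths["truth"], sep="\t", index_label="ID")
    sim.experiment.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample")
    return paths
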