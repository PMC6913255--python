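"""Method-agreement and truth-based performance statistics, plus the benchmark.

Set agreement uses the Jaccard coefficient with a fixed asymmetric
convention: set A is always the three-engine intersect and B the individual
method (or the union), so JC reads as "how close is this method to the
consensus core".  Fold-change agreement between engine pairs is summarised
by Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 sd of the
paired differences) and by the R^2 of a simple linear regression.  Against a
simulation truth set, PPV (precision), sensitivity (recall) and
FDR = 1 - PPV are reported.

``benchmark_study`` drives the full simulation experiment: for each
simulation repeat, replicate level and correction state it simulates counts,
runs the three engines through the consensus pipeline, and scores the five
gene sets (three engines, intersect, union), reporting per-cell means.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import multi_de_pairs, significant_sets
from .errors import ConfigError, DataError
from .simulate import NBParams, SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

SET_NAMES = ("edger", "deseq", "voom", "intersect", "union")
LOA_MULTIPLIER = 1.96


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; two empty sets are defined as fully agreeing (1.0)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(union)


def confusion_metrics(called: set, truth_positive: set) -> dict[str, float]:
    """PPV, sensitivity and FDR of a called set against the truth-positive set.

    Zero denominators yield NaN (with a warning), except sensitivity of an
    empty called set against a non-empty truth, which is 0.
    """
    called, truth_positive = set(called), set(truth_positive)
    tp = len(called & truth_positive)
    fp = len(called - truth_positive)
    fn = len(truth_positive - called)
    if tp + fp == 0:
        warnings.warn("no called positives; PPV/FDR undefined", stacklevel=2)
        ppv = fdr = float("nan")
    else:
        ppv = tp / (tp + fp)
        fdr = fp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no truth positives; sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    return {
        "PPV": ppv,
        "sensitivity": sens,
        "FDR": fdr,
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "size": len(called),
    }


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired logFC values from two methods."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    r2: float
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def bland_altman(x, y) -> AgreementStats:
    """Bias and 95% limits of agreement of x - y (paired by gene)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("Bland-Altman inputs must have equal length")
    if x.size < 2:
        raise DataError("Bland-Altman needs >=2 paired values")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias,
        sd=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        r2=logfc_r2(x, y) if x.size >= 3 else float("nan"),
        diffs=d,
        means=(x + y) / 2.0,
    )


def logfc_r2(x, y) -> float:
    """R^2 of the simple linear regression of y on x (= squared Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("logfc_r2 needs paired vectors of length >=3")
    if np.var(x) == 0:
        return float("nan")
    if np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass
class EvalReport:
    """Benchmark results.

    ``cells`` maps (set name, ruv flag, replicates) to per-metric lists of
    per-simulation values; ``agreement`` maps (method pair, ruv, replicates)
    to per-simulation Bland-Altman summaries.  ``means`` aggregates each
    cell; signed and absolute means are both reported for signed quantities.
    """

    cells: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    n_sims: int = 0

    def mean_metric(self, set_name: str, ruv: bool, reps: int, metric: str) -> float:
        values = np.asarray(self.cells[(set_name, ruv, reps)][metric], dtype=float)
        return float(np.nanmean(values)) if values.size else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (set_name, ruv, reps), metrics in self.cells.items():
            for metric, values in metrics.items():
                values = np.asarray(values, dtype=float)
                rows.append(
                    {
                        "set": set_name,
                        "ruv": ruv,
                        "replicates": reps,
                        "metric": metric,
                        "mean": float(np.nanmean(values)) if values.size else np.nan,
                        "mean_abs": float(np.nanmean(np.abs(values)))
                        if values.size
                        else np.nan,
                        "n_sims": int(np.isfinite(values).sum()),
                    }
                )
        for (pair_name, ruv, reps), stats_list in self.agreement.items():
            for metric in ("bias", "loa_lower", "loa_upper", "r2"):
                values = np.asarray(
                    [getattr(s, metric) for s in stats_list], dtype=float
                )
                rows.append(
                    {
                        "set": pair_name,
                        "ruv": ruv,
                        "replicates": reps,
                        "metric": metric,
                        "mean": float(np.nanmean(values)) if values.size else np.nan,
                        "mean_abs": float(np.nanmean(np.abs(values)))
                        if values.size
                        else np.nan,
                        "n_sims": int(np.isfinite(values).sum()),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "n_sims": self.n_sims,
            "failures": self.failures,
            "cells": [
                {
                    "set": set_name,
                    "ruv": ruv,
                    "replicates": reps,
                    "metrics": {k: list(map(float, v)) for k, v in metrics.items()},
                }
                for (set_name, ruv, reps), metrics in self.cells.items()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def score_merged(
    merged: pd.DataFrame, truth_de: set, alpha: float
) -> dict[str, dict[str, float]]:
    """Score the five gene sets of one merged table against a truth set."""
    sets = significant_sets(merged, alpha=alpha)
    intersect = sets["intersect"]
    out = {}
    for name in SET_NAMES:
        metrics = confusion_metrics(sets[name], truth_de)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics["JC"] = jaccard(intersect, sets[name])
        out[name] = metrics
    return out


def _engine_logfc(merged_engines) -> dict[str, np.ndarray]:
    return {
        res.role: res.table["logFC"].to_numpy() for res in merged_engines.values()
    }


def benchmark_study(
    config: SimConfig,
    params: NBParams,
    alpha: float = 0.05,
    replicate_levels: tuple[int, ...] = (3, 5),
    ruv_states: tuple[bool, ...] = (False, True),
    base_seed: int | None = None,
) -> EvalReport:
    """The full simulation benchmark.

    For each simulation repeat (child seed = base seed + repeat index) and
    replicate level, one dataset is simulated and analysed once without and,
    when requested, once with RUV correction (both states share the same
    counts, so the correction effect is paired).  Per cell the report holds
    JC to the intersect, FDR/PPV/sensitivity against truth and set size;
    pairwise Bland-Altman statistics are recorded per engine pair.
    """
    if base_seed is None:
        base_seed = config.seed if config.seed is not None else 0
    want_ruv = True in ruv_states
    report = EvalReport(n_sims=config.n_sims)
    for reps in replicate_levels:
        for name in SET_NAMES:
            for ruv in ruv_states:
                report.cells[(name, ruv, reps)] = {
                    m: [] for m in ("JC", "FDR", "PPV", "sensitivity", "size")
                }
    for sim_idx in range(config.n_sims):
        seed = int(base_seed) + sim_idx
        for reps in replicate_levels:
            sim_config = SimConfig(
                n_genes=config.n_genes,
                n_de=config.n_de,
                prop_up=config.prop_up,
                replicates=reps,
                n_sims=config.n_sims,
                lfc_range=config.lfc_range,
                libsize_sigma=config.libsize_sigma,
                seed=seed,
            )
            try:
                sim = simulate_experiment(sim_config, params, seed=seed)
                results = multi_de_pairs(sim.experiment, ruv=want_ruv, alpha=alpha)
                (pair_result,) = results.values()
                if pair_result.failed:
                    raise ConfigError(pair_result.error or "contrast failed")
            except Exception as exc:  # record, keep the remaining sims
                logger.error("simulation %d (reps=%d) failed: %s", sim_idx, reps, exc)
                report.failures.append(
                    {"sim": sim_idx, "replicates": reps, "error": str(exc)}
                )
                continue
            truth_de = sim.de_genes
            state_tables = {False: (pair_result.merged, pair_result.engines)}
            if want_ruv:
                state_tables[True] = (pair_result.merged_ruv, pair_result.engines_ruv)
            for ruv in ruv_states:
                merged, engines = state_tables[ruv]
                scores = score_merged(merged, truth_de, alpha)
                for name in SET_NAMES:
                    cell = report.cells[(name, ruv, reps)]
                    for metric in cell:
                        cell[metric].append(scores[name][metric])
                logfc = _engine_logfc(engines)
                for a, b in itertools.combinations(sorted(logfc), 2):
                    key = (f"{a}_vs_{b}", ruv, reps)
                    report.agreement.setdefault(key, []).append(
                        bland_altman(logfc[a], logfc[b])
                    )
    return report
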