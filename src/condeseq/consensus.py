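"""Consensus reduction: run every engine over every contrast, merge to one table.

The merged table is the toolkit's central deliverable.  Per gene it reports
the three engines' BH-adjusted p-values and significance ranks, the
consensus statistics p_intersect (largest adjusted p: a threshold on it
yields the intersect of the three DE sets), p_union (smallest adjusted p:
thresholding yields the union), rank_sum (sort key; small = consistently
significant), and the mean and standard deviation of the engines' log2 fold
changes.  Legacy column labels (edger_adj_p, deseq_adj_p, voom_adj_p, ...)
name the engine roles for schema compatibility with downstream tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .de_engines import (
    DEFAULT_NORM,
    ENGINES,
    DesignMatrix,
    EngineResult,
    build_design,
)
from .errors import CondeseqError, MergeError
from .experiment_io import ContrastPair, CountExperiment, enumerate_pairs, subset_for_pair
from .normalization import compute_factors
from .ruv import RUVFactors, augment_design, ruv_r

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["genename", "symbol", "kegg", "coords", "strand", "width"]

#: Merged-table column order (before optional annotation and flag columns).
MERGED_COLUMNS = [
    "ID",
    "AveExpr",
    "LogFC",
    "LogFC_sd",
    "edger_adj_p",
    "deseq_adj_p",
    "voom_adj_p",
    "edger_rank",
    "deseq_rank",
    "voom_rank",
    "rank_sum",
    "p_intersect",
    "p_union",
]


def merge_results(
    r1: EngineResult,
    r2: EngineResult,
    r3: EngineResult,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge exactly three engine results into the consensus table.

    Rows are sorted ascending by rank_sum (ties broken by gene ID).  A gene
    with an NA p-value in any engine gets NA p_intersect and na_flag = True;
    p_union is the minimum over the engines that produced a p-value.
    """
    results = {r.role: r for r in (r1, r2, r3)}
    if set(results) != {"edger", "deseq", "voom"}:
        raise MergeError(
            f"need one result per engine role, got {sorted(r.engine for r in (r1, r2, r3))}"
        )
    ids = results["edger"].table.index
    for role in ("deseq", "voom"):
        other = results[role].table.index
        if not other.equals(ids):
            diff = sorted(set(other) ^ set(ids))
            raise MergeError(f"gene sets differ between engines: {diff[:10]}")

    adj = {role: results[role].table["p_adj"].to_numpy() for role in results}
    ranks = {role: results[role].table["rank"].to_numpy() for role in results}
    logfc = np.column_stack([results[r].table["logFC"].to_numpy() for r in ("edger", "deseq", "voom")])
    ave = np.column_stack([results[r].table["AveExpr"].to_numpy() for r in ("edger", "deseq", "voom")])
    adj_stack = np.column_stack([adj["edger"], adj["deseq"], adj["voom"]])

    any_na = np.isnan(adj_stack).any(axis=1)
    all_na = np.isnan(adj_stack).all(axis=1)
    with np.errstate(all="ignore"):
        p_union = np.nanmin(adj_stack, axis=1, initial=np.inf)
    p_union = np.where(all_na, np.nan, np.where(np.isinf(p_union), np.nan, p_union))
    p_intersect = np.where(any_na, np.nan, adj_stack.max(axis=1))

    merged = pd.DataFrame(
        {
            "ID": ids,
            "AveExpr": ave.mean(axis=1),
            "LogFC": logfc.mean(axis=1),
            "LogFC_sd": logfc.std(axis=1, ddof=1),
            "edger_adj_p": adj["edger"],
            "deseq_adj_p": adj["deseq"],
            "voom_adj_p": adj["voom"],
            "edger_rank": ranks["edger"],
            "deseq_rank": ranks["deseq"],
            "voom_rank": ranks["voom"],
            "rank_sum": ranks["edger"] + ranks["deseq"] + ranks["voom"],
            "p_intersect": p_intersect,
            "p_union": p_union,
        }
    )
    if annotations is not None:
        for col in ANNOTATION_COLUMNS:
            if col in annotations.columns:
                merged[col] = (
                    merged["ID"].map(annotations[col]).fillna("").astype(str)
                )
            else:
                merged[col] = ""
    merged["na_flag"] = any_na
    merged = merged.sort_values(
        ["rank_sum", "ID"], ascending=True, kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return merged


def significant_sets(merged: pd.DataFrame, alpha: float = 0.05) -> dict[str, set]:
    """Per-engine, intersect and union DE gene sets at adjusted p <= alpha."""
    if not 0 < alpha < 1:
        raise MergeError(f"alpha must be in (0, 1), got {alpha}")
    ids = merged["ID"]
    out = {}
    for role in ("edger", "deseq", "voom"):
        out[role] = set(ids[merged[f"{role}_adj_p"] <= alpha])
    out["intersect"] = set(ids[merged["p_intersect"] <= alpha])
    out["union"] = set(ids[merged["p_union"] <= alpha])
    return out


@dataclass
class PairResult:
    """All per-contrast outputs of a multi-engine run."""

    pair: ContrastPair
    merged: pd.DataFrame | None = None
    merged_ruv: pd.DataFrame | None = None
    engines: dict[str, EngineResult] = field(default_factory=dict)
    engines_ruv: dict[str, EngineResult] = field(default_factory=dict)
    ruv_factors: RUVFactors | None = None
    failed: bool = False
    error: str | None = None


def _run_engines(exp, pair, design, norm_method):
    results = {}
    sub = subset_for_pair(exp, pair)
    for name, fit in ENGINES.items():
        method = DEFAULT_NORM[name] if norm_method == "all_defaults" else norm_method
        norm = compute_factors(sub.counts, method)
        results[name] = fit(exp, pair, design=design, norm=norm)
    return results


def multi_de_pairs(
    exp: CountExperiment,
    ruv: bool = False,
    alpha: float = 0.05,
    norm_method: str = "all_defaults",
    k: int = 1,
    annotations: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, PairResult]:
    """Run all three engines (optionally with RUVr) over every group pair.

    With ``ruv`` the unwanted-variation factors are estimated once per
    contrast from the supervised design and the identical W is appended to
    every engine's design before the corrected re-run, so the engines are
    compared under the same correction.  A failing contrast is recorded and
    the remaining contrasts proceed.
    """
    annotations = annotations if annotations is not None else exp.annotations
    results: dict[str, PairResult] = {}
    for pair in enumerate_pairs(exp):
        res = PairResult(pair=pair)
        try:
            sub = subset_for_pair(exp, pair)
            design = build_design(sub.sample_meta, pair)
            res.engines = _run_engines(exp, pair, design, norm_method)
            res.merged = merge_results(
                *res.engines.values(), annotations=annotations
            )
            if ruv:
                res.ruv_factors = ruv_r(exp, pair, design=design, k=k)
                aug = augment_design(design, res.ruv_factors)
                res.engines_ruv = _run_engines(exp, pair, aug, norm_method)
                res.merged_ruv = merge_results(
                    *res.engines_ruv.values(), annotations=annotations
                )
        except CondeseqError as exc:
            res.failed = True
            res.error = str(exc)
            logger.error("contrast %s failed: %s", pair.name, exc)
        results[pair.name] = res

    if output_dir is not None:
        write_merged_tables(results, output_dir)
    return results


def write_merged_tables(results: dict[str, PairResult], output_dir) -> list[Path]:
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, res in results.items():
        if res.merged is not None:
            path = outdir / f"{name}.tsv"
            res.merged.to_csv(path, sep="\t", index=False)
            written.append(path)
        if res.merged_ruv is not None:
            path = outdir / f"{name}.ruv.tsv"
            res.merged_ruv.to_csv(path, sep="\t", index=False)
            written.append(path)
    for p in written:
        logger.info("wrote merged table: %s", p)
    return written


def failure_summary(results: dict[str, PairResult]) -> dict[str, str]:
    return {name: res.error for name, res in results.items() if res.failed}
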