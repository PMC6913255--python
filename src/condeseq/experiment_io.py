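"""Sample tables, count matrices and contrast enumeration.

This is the ``build`` stage of the workflow: a delimited sample table names
the count source for each sample (an HTSeq two-column file or a column of a
gene x sample matrix) together with its group label, optional subject pairing
and optional technical-replicate key.  The result is a
:class:`CountExperiment` holding an integer count matrix aligned to validated
sample metadata, from which all pairwise group contrasts are enumerated.

BAM/SAM handling is deliberately out of scope: counting reads is commodity
upstream work and the statistics here start at the count matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, DesignError, SchemaError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("file", "group")
OPTIONAL_COLUMNS = ("pairs", "tech_replicate")

#: Leading string marking HTSeq summary rows (__no_feature, __ambiguous, ...)
HTSEQ_SPECIAL_PREFIX = "__"


@dataclass
class SampleTable:
    """Validated experimental design table.

    ``data`` has columns ``file`` and ``group`` and, when provided,
    ``pairs`` (subject identifier for paired designs) and ``tech_replicate``
    (replicate-merge key).  Rows are kept in input order; that order defines
    the column order of the count matrix.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_sample_table(self.data)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].astype(str).unique())

    @property
    def files(self) -> list[str]:
        return list(self.data["file"].astype(str))

    @property
    def has_pairs(self) -> bool:
        return "pairs" in self.data.columns and self.data["pairs"].notna().any()

    @property
    def has_tech_replicates(self) -> bool:
        return (
            "tech_replicate" in self.data.columns
            and self.data["tech_replicate"].notna().any()
        )

    def __len__(self) -> int:
        return len(self.data)


def validate_sample_table(data: pd.DataFrame) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in data.columns:
            raise SchemaError(f"sample table is missing mandatory column {col!r}")
    if data["file"].duplicated().any():
        dups = sorted(data.loc[data["file"].duplicated(), "file"].unique())
        raise SchemaError(f"duplicate 'file' entries in sample table: {dups}")
    n_groups = data["group"].astype(str).nunique()
    if n_groups < 2:
        raise DesignError(
            f"sample table defines {n_groups} group(s); at least 2 are required"
        )
    if "pairs" in data.columns and data["pairs"].notna().any():
        sub = data.loc[data["pairs"].notna()]
        per_pair = sub.groupby(sub["pairs"].astype(str))["group"].nunique()
        bad = sorted(per_pair.index[per_pair < 2])
        if bad:
            raise DesignError(
                "each pair identifier must appear in >=2 groups; "
                f"violated by: {bad}"
            )


def read_sample_table(path: str | Path, dialect: str | None = None) -> SampleTable:
    """Read a CSV/TSV sample table with header (file, group[, pairs][, tech_replicate]).

    ``dialect`` is the field delimiter; when None it is sniffed from the file
    extension ('.csv' -> comma, otherwise tab).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"sample table not found: {path}")
    if dialect is None:
        dialect = "," if path.suffix.lower() == ".csv" else "\t"
    data = pd.read_csv(path, sep=dialect, dtype=str, skipinitialspace=True)
    data.columns = [c.strip().lower() for c in data.columns]
    keep = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in data.columns]
    return SampleTable(data[keep].copy())


@dataclass
class CountExperiment:
    """Integer gene x sample count matrix plus aligned sample metadata.

    ``counts``: DataFrame indexed by gene ID with one column per retained
    sample, in sample-table order.  ``sample_meta``: one row per counts
    column (index = sample name).  ``annotations``: optional gene annotation
    table indexed by gene ID (genename, symbol, kegg, coords, strand, width).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise DataError("counts columns do not match sample_meta rows")
        if self.counts.index.duplicated().any():
            dups = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise DataError(f"duplicate gene IDs: {dups[:10]}")
        values = self.counts.to_numpy()
        if np.issubdtype(values.dtype, np.floating):
            if not np.allclose(values, np.round(values)):
                bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise DataError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_meta["group"].astype(str).unique())

    def subset_samples(self, names: list[str]) -> "CountExperiment":
        return CountExperiment(
            counts=self.counts[names].copy(),
            sample_meta=self.sample_meta.loc[names].copy(),
            annotations=self.annotations,
        )


@dataclass(frozen=True)
class ContrastPair:
    """One unordered group pair; logFC convention is log2(group_b / group_a)."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise DesignError("contrast groups must differ")

    @property
    def name(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


def _read_htseq_file(path: Path) -> pd.Series:
    try:
        table = pd.read_csv(
            path, sep="\t", header=None, names=["gene", "count"], dtype={"gene": str}
        )
    except FileNotFoundError:
        raise AlignmentError(f"HTSeq count file not found: {path}") from None
    special = table["gene"].str.startswith(HTSEQ_SPECIAL_PREFIX)
    if special.any():
        logger.info(
            "dropped %d HTSeq summary rows from %s: %s",
            int(special.sum()),
            path.name,
            ", ".join(table.loc[special, "gene"]),
        )
        table = table.loc[~special]
    return table.set_index("gene")["count"]


def load_counts(
    table: SampleTable,
    source: str = "htseq",
    matrix_path: str | Path | None = None,
    base_dir: str | Path | None = None,
    annotations: pd.DataFrame | None = None,
) -> CountExperiment:
    """Assemble a CountExperiment from HTSeq files or a matrix file.

    source='htseq': the ``file`` column names one two-column tab-delimited
    count file per sample (resolved relative to ``base_dir`` when given).
    All files must share an identical gene-ID set; gene order is taken from
    the first file.  ``__``-prefixed summary rows are dropped (and logged).

    source='matrix': ``matrix_path`` is a delimited gene x sample matrix
    whose header contains every ``file`` entry of the sample table; columns
    are reordered to sample-table order.
    """
    sample_names = table.files
    if source == "htseq":
        base = Path(base_dir) if base_dir is not None else Path(".")
        series = {}
        for name in sample_names:
            p = Path(name)
            if not p.is_absolute():
                p = base / p
            series[name] = _read_htseq_file(p)
        first = sample_names[0]
        ref_ids = series[first].index
        for name in sample_names[1:]:
            if not series[name].index.equals(ref_ids):
                diff = sorted(set(series[name].index) ^ set(ref_ids))
                raise AlignmentError(
                    f"gene IDs of {name!r} disagree with {first!r}; "
                    f"symmetric difference: {diff[:10]}"
                )
        counts = pd.DataFrame({n: series[n] for n in sample_names}).loc[ref_ids]
    elif source == "matrix":
        if matrix_path is None:
            raise SchemaError("source='matrix' requires matrix_path")
        sep = "," if str(matrix_path).endswith(".csv") else "\t"
        mat = pd.read_csv(matrix_path, sep=sep, index_col=0)
        mat.index = mat.index.astype(str)
        missing = [n for n in sample_names if n not in mat.columns]
        if missing:
            raise AlignmentError(
                f"matrix file lacks columns referenced by the sample table: {missing}"
            )
        counts = mat[sample_names]
    else:
        raise SchemaError(f"unknown count source {source!r}")

    meta = table.data.copy()
    meta.index = pd.Index(sample_names, name="sample")
    return CountExperiment(counts=counts, sample_meta=meta, annotations=annotations)


def merge_technical_replicates(exp: CountExperiment) -> CountExperiment:
    """Sum counts of samples sharing a tech_replicate key.

    The merged sample inherits the group (and pairs) of its members, which
    must agree within a key; rows without a key are untouched.  Total counts
    per merge group are conserved.
    """
    meta = exp.sample_meta
    if "tech_replicate" not in meta.columns or meta["tech_replicate"].isna().all():
        return exp

    key = meta["tech_replicate"].astype(object).copy()
    solo = key.isna()
    key[solo] = [f"__solo_{name}" for name in meta.index[solo]]

    new_cols, new_meta_rows = [], []
    seen: set[str] = set()
    for k in key:  # preserve first-appearance order
        if k in seen:
            continue
        seen.add(k)
        members = list(meta.index[key == k])
        sub = meta.loc[members]
        if sub["group"].nunique() > 1:
            raise DesignError(
                f"tech_replicate key {k!r} spans groups "
                f"{sorted(sub['group'].unique())}"
            )
        if "pairs" in sub.columns and sub["pairs"].dropna().nunique() > 1:
            raise DesignError(f"tech_replicate key {k!r} spans multiple pairs")
        name = members[0] if len(members) == 1 else str(k)
        new_cols.append((name, exp.counts[members].sum(axis=1)))
        row = sub.iloc[0].copy()
        row["file"] = name
        row.name = name
        new_meta_rows.append(row)

    counts = pd.DataFrame(dict(new_cols))
    new_meta = pd.DataFrame(new_meta_rows)
    new_meta.index.name = "sample"
    new_meta = new_meta.drop(columns=["tech_replicate"], errors="ignore")
    return CountExperiment(
        counts=counts, sample_meta=new_meta, annotations=exp.annotations
    )


def enumerate_pairs(exp: CountExperiment) -> list[ContrastPair]:
    """All unordered group pairs in deterministic lexicographic order."""
    groups = exp.groups
    if len(groups) < 2:
        raise DesignError("at least 2 groups are required to form contrasts")
    return [ContrastPair(a, b) for a, b in itertools.combinations(groups, 2)]


def subset_for_pair(exp: CountExperiment, pair: ContrastPair) -> CountExperiment:
    """Restrict the experiment to the samples of one contrast, keeping order."""
    for g in (pair.group_a, pair.group_b):
        if g not in exp.groups:
            raise DesignError(f"group {g!r} not present in experiment")
    mask = exp.sample_meta["group"].astype(str).isin([pair.group_a, pair.group_b])
    return exp.subset_samples(list(exp.sample_meta.index[mask]))


def write_experiment(exp: CountExperiment, outdir: str | Path) -> dict[str, Path]:
    """Serialize as gene x sample TSV + sample-table TSV side-car."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
    }
    exp.counts.to_csv(paths["counts"], sep="\t", index_label="ID")
    exp.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample")
    if exp.annotations is not None:
        paths["annotations"] = outdir / "annotations.tsv"
        exp.annotations.to_csv(paths["annotations"], sep="\t", index_label="ID")
    for k, p in paths.items():
        logger.info("wrote %s: %s", k, p)
    return paths


def read_experiment(indir: str | Path) -> CountExperiment:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0, dtype=str)
    annot_path = indir / "annotations.tsv"
    annotations = (
        pd.read_csv(annot_path, sep="\t", index_col=0) if annot_path.exists() else None
    )
    return CountExperiment(counts=counts, sample_meta=meta, annotations=annotations)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (ID plus any of genename, symbol, kegg,
    coords, strand, width)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    annot = pd.read_csv(path, sep=sep, index_col=0)
    annot.index = annot.index.astype(str)
    return annot
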