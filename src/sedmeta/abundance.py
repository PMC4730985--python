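"""Count tables, normalization and RNA-vs-DNA expression statistics.

Implements the quantitative layer of a paired metatranscriptome (RNA) /
metagenome (DNA) comparison: relative abundance as percent of annotated reads,
counts per million (CPM), without-replacement subsampling to a common depth,
the per-category expressed fraction (share of DNA-detected functions also
detected in RNA), the two headline overlap ratios, top-N function rankings and
taxon x category crosstabs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hits import UNASSIGNED, QueryAssignment
from .ontology import FunctionOntology, rollup_counts

__all__ = [
    "CountTable",
    "DatasetPair",
    "counts_from_mapping",
    "relative_abundance",
    "cpm",
    "subsample_counts",
    "exclude_functions",
    "expressed_fraction",
    "overlap_stats",
    "top_functions",
    "taxon_function_crosstab",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass
class CountTable:
    """Non-negative read counts for one dataset at one unit of aggregation.

    ``total_annotated`` is the denominator for relative abundance and CPM —
    the number of reads annotated in this dataset.  Reads mapped to
    unannotated features are tracked in ``unannotated`` and never enter the
    denominator.
    """

    dataset_id: str
    unit: str  # orf | function | category | taxon | taxon_function
    counts: dict[str, int] = field(default_factory=dict)
    total_annotated: int = 0
    unannotated: int = 0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative counts not allowed: {bad}")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], dataset_id: str = "", unit: str = "function"
    ) -> "CountTable":
        counts = dict(counts)
        return cls(dataset_id, unit, counts, total_annotated=int(sum(counts.values())))

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def detected(self) -> set[str]:
        """Keys with at least one read."""
        return {k for k, v in self.counts.items() if v > 0}


@dataclass
class DatasetPair:
    """An RNA (metatranscriptome) / DNA (metagenome) count-table pair."""

    rna: CountTable
    dna: CountTable

    def __post_init__(self) -> None:
        if self.rna.unit != self.dna.unit:
            raise ValueError(
                f"unit mismatch: rna={self.rna.unit!r} vs dna={self.dna.unit!r}"
            )


# -- building tables -----------------------------------------------------


def counts_from_mapping(
    read_assignments: Iterable[tuple[str, str]],
    annotations: Mapping[str, object] | None = None,
    dataset_id: str = "",
) -> CountTable:
    """Per-ORF counts from (read_id, orf_id) pairs.

    Each read must appear exactly once (multi-mapping is assumed resolved
    upstream); duplicate read ids are rejected.  When ``annotations`` is
    given, reads to ORFs absent from it are excluded from the table and from
    ``total_annotated`` but tallied in ``unannotated``.
    """
    counts: dict[str, int] = {}
    seen: set[str] = set()
    unannotated = 0
    for read_id, orf_id in read_assignments:
        if read_id in seen:
            raise ValueError(f"duplicate read_id {read_id!r}")
        seen.add(read_id)
        if annotations is not None and orf_id not in annotations:
            unannotated += 1
            continue
        counts[orf_id] = counts.get(orf_id, 0) + 1
    table = CountTable.from_counts(counts, dataset_id=dataset_id, unit="orf")
    table.unannotated = unannotated
    return table


def load_counts_tsv(source: str | Path | IO[str], dataset_id: str = "", unit: str = "orf") -> CountTable:
    """Pre-aggregated counts TSV: key<TAB>count, '#' comments and an optional
    header row allowed."""
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = open(source, "rt", encoding="utf-8"), True
    counts: dict[str, int] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns (key, count)")
            if fields[1] in ("count", "reads"):
                continue
            counts[fields[0]] = counts.get(fields[0], 0) + int(fields[1])
    finally:
        if close:
            handle.close()
    return CountTable.from_counts(counts, dataset_id=dataset_id, unit=unit)


def aggregate_by(
    table: CountTable, key_map: Mapping[str, Iterable[str]], unit: str
) -> CountTable:
    """Re-aggregate a table through a key -> group(s) mapping (e.g. ORF ->
    functions).  A key mapped to several groups contributes its full count to
    each; unmapped keys accumulate in ``unannotated``."""
    out: dict[str, int] = {}
    unannotated = table.unannotated
    total = 0
    for key, count in table.counts.items():
        groups = list(key_map.get(key, ()))
        if not groups:
            unannotated += count
            continue
        total += count
        for g in sorted(set(groups)):
            out[g] = out.get(g, 0) + count
    result = CountTable(table.dataset_id, unit, out, total_annotated=total)
    result.unannotated = unannotated
    return result


# -- normalization -------------------------------------------------------


def relative_abundance(table: CountTable) -> dict[str, float]:
    """Percent of the dataset's annotated reads, per key; sums to 100."""
    if table.total_annotated <= 0:
        raise ValueError("relative_abundance requires total_annotated > 0")
    denom = float(table.total_annotated)
    return {k: 100.0 * v / denom for k, v in table.counts.items()}


def cpm(table: CountTable) -> dict[str, float]:
    """Counts per million annotated reads, per key; sums to 1e6."""
    if table.total_annotated <= 0:
        raise ValueError("cpm requires total_annotated > 0")
    denom = float(table.total_annotated)
    return {k: 1e6 * v / denom for k, v in table.counts.items()}


def subsample_counts(
    table: CountTable, depth: int, seed: int | np.random.Generator | None = None
) -> CountTable:
    """Draw exactly ``depth`` reads without replacement (multivariate
    hypergeometric); reproducible for a fixed seed."""
    total = table.total
    if not 0 <= depth <= total:
        raise ValueError(f"depth must be in [0, {total}], got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = sorted(table.counts)
    colors = np.array([table.counts[k] for k in keys], dtype=np.int64)
    if len(keys) == 0:
        draw = np.array([], dtype=np.int64)
    else:
        draw = rng.multivariate_hypergeometric(colors, depth, method="marginals")
    sub = {k: int(c) for k, c in zip(keys, draw)}
    out = replace(table, counts=sub, total_annotated=int(depth))
    return out


# -- filtering -----------------------------------------------------------


def exclude_functions(
    table: CountTable,
    blacklist: Iterable[str],
    ontology: FunctionOntology | None = None,
) -> CountTable:
    """Drop blacklisted functions from a function-level table.

    The blacklist matches function ids directly and, when an ontology is
    supplied, function names (case-sensitive exact).  ``total_annotated`` is
    reduced by the removed counts.  Used e.g. to drop the "Retron-type reverse
    transcriptase" role, a known rRNA misannotation sink.
    """
    wanted = set(blacklist)
    if ontology is not None:
        wanted |= ontology.ids_for_names(wanted)
    removed = sum(v for k, v in table.counts.items() if k in wanted)
    kept = {k: v for k, v in table.counts.items() if k not in wanted}
    return replace(table, counts=kept, total_annotated=table.total_annotated - removed)


# -- RNA vs DNA statistics -----------------------------------------------


def expressed_fraction(
    pair: DatasetPair,
    ontology: FunctionOntology,
    level: int = 1,
) -> pd.DataFrame:
    """Per-category expressed fraction: of the functions detected (>=1 read)
    in the metagenome, the share also detected in the metatranscriptome.

    Returns a DataFrame with columns ``category``, ``n_expressed``,
    ``n_total``, ``percent`` (whole-percent, half-up).  Categories whose DNA
    detection count is zero are reported with ``percent`` = NaN (undefined),
    never 0.
    """
    if pair.rna.unit != "function" or pair.dna.unit != "function":
        raise ValueError("expressed_fraction requires function-level tables")
    dna_detected = pair.dna.detected()
    rna_detected = pair.rna.detected()
    categories: set[str] = set()
    for fid in dna_detected | rna_detected:
        categories |= ontology.categories_at(fid, level)
    rows = []
    for cat in sorted(categories):
        in_cat_dna = {f for f in dna_detected if cat in ontology.categories_at(f, level)}
        n_total = len(in_cat_dna)
        n_expressed = len(in_cat_dna & rna_detected)
        pct = round_half_up(100.0 * n_expressed / n_total) if n_total else float("nan")
        rows.append((cat, n_expressed, n_total, pct))
    return pd.DataFrame(rows, columns=["category", "n_expressed", "n_total", "percent"])


def expressed_percent(n_expressed: int, n_total: int) -> int:
    """Whole-percent (half-up) expressed ratio for one category."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_expressed / n_total)


def overlap_stats(pair: DatasetPair) -> tuple[float | None, float | None]:
    """The two headline overlap ratios between function repertoires.

    Returns ``(pct_dna_functions_expressed, pct_rna_functions_confirmed)``:
    percent of DNA-detected functions also seen in RNA, and percent of
    RNA-detected functions also seen in DNA.  A component is None (undefined)
    when its denominator set is empty.
    """
    if pair.rna.unit != "function" or pair.dna.unit != "function":
        raise ValueError("overlap_stats requires function-level tables")
    f_dna = pair.dna.detected()
    f_rna = pair.rna.detected()
    inter = len(f_dna & f_rna)
    pct_expressed = 100.0 * inter / len(f_dna) if f_dna else None
    pct_confirmed = 100.0 * inter / len(f_rna) if f_rna else None
    return pct_expressed, pct_confirmed


def top_functions(table: CountTable, n: int) -> list[tuple[str, int]]:
    """The ``n`` most abundant keys, descending by count, ties broken
    lexicographically by key."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def taxon_function_crosstab(
    assignments: Sequence[QueryAssignment],
    read_counts: Mapping[str, int],
    ontology: FunctionOntology,
    level: int = 1,
    collapse: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Taxon x category read-count matrix.

    Per taxon row, function counts are rolled up with the same-parent
    deduplication rule.  ``collapse`` optionally maps assigned taxon ids to
    display taxa (e.g. phylum with proteobacterial classes split out);
    unmapped taxa keep their own id.  UNASSIGNED queries are excluded from the
    matrix; their read total is returned alongside.
    """
    per_taxon_fn: dict[str, dict[str, int]] = {}
    unassigned_reads = 0
    for a in assignments:
        reads = int(read_counts.get(a.query_id, 0))
        if a.taxon_id == UNASSIGNED:
            unassigned_reads += reads
            continue
        taxon = collapse.get(a.taxon_id, a.taxon_id) if collapse else a.taxon_id
        fn_counts = per_taxon_fn.setdefault(taxon, {})
        for fid in a.function_ids:
            fn_counts[fid] = fn_counts.get(fid, 0) + reads
    rows = {
        taxon: rollup_counts(fn_counts, ontology, level)
        for taxon, fn_counts in per_taxon_fn.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df.sort_index().sort_index(axis=1)
    df.index.name = "taxon"
    return df, unassigned_reads
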