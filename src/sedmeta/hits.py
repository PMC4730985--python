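"""Homology-hit processing: parsing, score-window filtering, taxon and function assignment.

Consumes 12-column BLAST tabular ("outfmt 6") hit files.  A query's taxon is
assigned either by the LCA rule — the most specific taxon common to all hits
with bit score above an absolute threshold (default >50) and above a fraction
(default >0.9) of the best hit's score — or by best hit, with score ties
collapsing to the LCA of the tied taxa.  Functions come from the best-scoring
annotated hit above the absolute threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .taxonomy import TaxonomyTree

__all__ = [
    "AlignmentHit",
    "SubjectMeta",
    "QueryAssignment",
    "UNASSIGNED",
    "HitParseError",
    "read_tabular_hits",
    "load_subject_meta",
    "filter_hits_score_window",
    "dedupe_best_per_subject",
    "assign_taxon_lca",
    "assign_taxon_best_hit",
    "assign_function",
    "assign_query",
]

logger = logging.getLogger(__name__)

#: sentinel taxon for queries with no usable hits
UNASSIGNED = "UNASSIGNED"

#: default absolute bit-score threshold (strict: score must exceed it)
DEFAULT_MIN_BIT_SCORE = 50.0
#: default top-score window fraction (strict: score must exceed fraction x best)
DEFAULT_WINDOW_FRACTION = 0.9


class HitParseError(ValueError):
    """Malformed line in a tabular hit file; message carries the 1-based line number."""


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column BLAST tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (self.bit_score >= 0 and self.bit_score == self.bit_score):
            raise ValueError(f"bit_score must be finite and >=0, got {self.bit_score}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >=1, got {self.alignment_length}")


@dataclass
class SubjectMeta:
    """Cross-reference from subject (reference gene) ids to taxon and function ids."""

    taxon: dict[str, str] = field(default_factory=dict)
    functions: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.taxon

    def add(self, subject_id: str, taxon_id: str, function_ids: Iterable[str] = ()) -> None:
        self.taxon[subject_id] = taxon_id
        self.functions[subject_id] = frozenset(function_ids)


@dataclass(frozen=True)
class QueryAssignment:
    """Taxon + function assignment for one query sequence."""

    query_id: str
    taxon_id: str  # UNASSIGNED when no hit survived filtering
    function_ids: frozenset[str] = frozenset()
    n_hits_considered: int = 0


# -- parsing -------------------------------------------------------------


def _parse_hit_line(line: str, lineno: int) -> AlignmentHit:
    fields = line.split("\t")
    if len(fields) != 12:
        raise HitParseError(f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
    try:
        return AlignmentHit(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=float(fields[2]),
            alignment_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            q_start=int(fields[6]),
            q_end=int(fields[7]),
            s_start=int(fields[8]),
            s_end=int(fields[9]),
            e_value=float(fields[10]),
            bit_score=float(fields[11]),
        )
    except (ValueError, TypeError) as exc:
        raise HitParseError(f"line {lineno}: {exc}") from exc


def read_tabular_hits(source: str | Path | IO[str]) -> list[tuple[str, list[AlignmentHit]]]:
    """Read a 12-column tabular hit file, grouped by query id.

    Groups follow first-appearance order; a query's rows split across the file
    are merged into one group.
    """
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = open(source, "rt", encoding="utf-8"), True
    groups: dict[str, list[AlignmentHit]] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hit = _parse_hit_line(line, lineno)
            groups.setdefault(hit.query_id, []).append(hit)
    finally:
        if close:
            handle.close()
    return list(groups.items())


def load_subject_meta(source: str | Path | IO[str]) -> SubjectMeta:
    """Subject metadata TSV: subject_id, taxon_id, comma-separated function ids."""
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = open(source, "rt", encoding="utf-8"), True
    meta = SubjectMeta()
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "subject_id" and lineno == 1:
                continue
            if len(fields) < 2:
                raise HitParseError(f"line {lineno}: expected >=2 columns in subject metadata")
            funcs = [f for f in fields[2].split(",") if f] if len(fields) > 2 else []
            meta.add(fields[0], fields[1], funcs)
    finally:
        if close:
            handle.close()
    return meta


# -- filtering -----------------------------------------------------------


def filter_hits_score_window(
    hits: Sequence[AlignmentHit],
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> list[AlignmentHit]:
    """Keep hits with bit score strictly above the absolute threshold and
    strictly above ``window_fraction`` times the best hit's score.

    The best-scoring hit is always retained when it clears the absolute
    threshold (relevant only at window_fraction == 1, where the strict window
    inequality would otherwise discard it).
    """
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    passing = [h for h in hits if h.bit_score > min_bit_score]
    if not passing:
        return []
    best = max(h.bit_score for h in passing)
    bound = window_fraction * best
    return [h for h in passing if h.bit_score > bound or h.bit_score == best]


def dedupe_best_per_subject(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse multiple HSPs to the same subject, keeping the max-score HSP.

    Output preserves first-appearance order of subjects.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.subject_id)
        if cur is None or h.bit_score > cur.bit_score:
            best[h.subject_id] = h
    return list(best.values())


# -- assignment ----------------------------------------------------------


def _hit_taxa(
    hits: Sequence[AlignmentHit],
    meta: SubjectMeta,
    missing_subject: str,
) -> list[tuple[AlignmentHit, str]]:
    out = []
    for h in hits:
        taxon = meta.taxon.get(h.subject_id)
        if taxon is None:
            if missing_subject == "error":
                raise KeyError(f"subject {h.subject_id!r} absent from subject metadata")
            logger.debug("skipping hit to unknown subject %r", h.subject_id)
            continue
        out.append((h, taxon))
    return out


def assign_taxon_lca(
    query_id: str,
    retained_hits: Sequence[AlignmentHit],
    meta: SubjectMeta,
    tree: TaxonomyTree,
    missing_subject: str = "skip",
) -> QueryAssignment:
    """Assign the LCA of the distinct taxa of the retained hits.

    ``retained_hits`` are expected to be pre-filtered by
    :func:`filter_hits_score_window`.  Queries with no usable hits are
    UNASSIGNED.
    """
    usable = _hit_taxa(retained_hits, meta, missing_subject)
    if not usable:
        return QueryAssignment(query_id, UNASSIGNED, frozenset(), 0)
    taxa = {t for _, t in usable}
    return QueryAssignment(query_id, tree.lca(taxa), frozenset(), len(usable))


def assign_taxon_best_hit(
    query_id: str,
    retained_hits: Sequence[AlignmentHit],
    meta: SubjectMeta,
    tree: TaxonomyTree,
    missing_subject: str = "skip",
) -> QueryAssignment:
    """Assign the taxon of the unique max-score hit; ties collapse to the LCA
    of the tied hits' taxa."""
    usable = _hit_taxa(retained_hits, meta, missing_subject)
    if not usable:
        return QueryAssignment(query_id, UNASSIGNED, frozenset(), 0)
    best = max(h.bit_score for h, _ in usable)
    tied = {t for h, t in usable if h.bit_score == best}
    return QueryAssignment(query_id, tree.lca(tied), frozenset(), len(usable))


def assign_function(
    hits: Sequence[AlignmentHit],
    meta: SubjectMeta,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
) -> frozenset[str]:
    """Function set of the best-scoring annotated hit above the threshold.

    Hits whose subject has no functions are passed over in favour of the next
    best annotated hit; empty set when no passing hit is annotated.  Score ties
    break on subject id for determinism.
    """
    passing = sorted(
        (h for h in hits if h.bit_score > min_bit_score),
        key=lambda h: (-h.bit_score, h.subject_id),
    )
    for h in passing:
        funcs = meta.functions.get(h.subject_id)
        if funcs:
            return funcs
    return frozenset()


def assign_query(
    query_id: str,
    hits: Sequence[AlignmentHit],
    meta: SubjectMeta,
    tree: TaxonomyTree,
    mode: str = "lca",
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    missing_subject: str = "skip",
) -> QueryAssignment:
    """Full per-query pipeline: HSP dedup, score-window filter, taxon + function."""
    deduped = dedupe_best_per_subject(hits)
    retained = filter_hits_score_window(deduped, min_bit_score, window_fraction)
    if mode == "lca":
        assigned = assign_taxon_lca(query_id, retained, meta, tree, missing_subject)
    elif mode == "best_hit":
        assigned = assign_taxon_best_hit(query_id, retained, meta, tree, missing_subject)
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    funcs = assign_function(deduped, meta, min_bit_score)
    return QueryAssignment(query_id, assigned.taxon_id, funcs, assigned.n_hits_considered)
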