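"""Three-level functional ontology (SEED-subsystem style) and count rollup.

A function (protein role) may belong to several (level1, level2, level3)
category paths.  When counts are summarised at a higher level, a function
contributes its count at most once per category — duplicate affiliations under
the same parent are collapsed — but still contributes to every distinct
category it belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

__all__ = [
    "FunctionEntry",
    "FunctionOntology",
    "OntologyParseError",
    "UNCLASSIFIED",
    "load_ontology",
    "rollup_counts",
]

#: reserved category for counted functions absent from the ontology
UNCLASSIFIED = "unclassified"

CategoryPath = tuple[str, str, str]


class OntologyParseError(ValueError):
    pass


@dataclass
class FunctionEntry:
    """One function with its (possibly multiple) category membership paths."""

    function_id: str
    name: str = ""
    paths: tuple[CategoryPath, ...] = ()

    def categories_at(self, level: int) -> set[str]:
        """Distinct category labels this function belongs to at a level (1-3)."""
        if level not in (1, 2, 3):
            raise ValueError(f"level must be 1, 2 or 3, got {level}")
        return {p[level - 1] for p in self.paths}


class FunctionOntology:
    """Map of function_id -> :class:`FunctionEntry` with multi-path merging."""

    def __init__(self, entries: Iterable[FunctionEntry] = ()):
        self.entries: dict[str, FunctionEntry] = {}
        for e in entries:
            self.add(e.function_id, e.name, e.paths)

    def add(self, function_id: str, name: str, paths: Iterable[CategoryPath]) -> None:
        entry = self.entries.get(function_id)
        if entry is None:
            entry = FunctionEntry(function_id, name, ())
            self.entries[function_id] = entry
        if name and not entry.name:
            entry.name = name
        for p in paths:
            if p not in entry.paths:  # identical duplicate paths collapse
                entry.paths = entry.paths + (p,)

    def __contains__(self, function_id: str) -> bool:
        return function_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def categories_at(self, function_id: str, level: int) -> set[str]:
        entry = self.entries.get(function_id)
        if entry is None:
            return {UNCLASSIFIED}
        return entry.categories_at(level)

    def ids_for_names(self, names: Iterable[str]) -> set[str]:
        wanted = set(names)
        return {fid for fid, e in self.entries.items() if e.name in wanted}


def load_ontology(source: str | Path | IO[str]) -> FunctionOntology:
    """Ontology TSV: function_id, level1, level2, level3, function_name.

    One membership path per row; rows sharing a function_id merge into one
    entry with multiple paths.  An empty level-1 cell is a parse error.
    """
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = open(source, "rt", encoding="utf-8"), True
    onto = FunctionOntology()
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "function_id":
                continue
            if len(fields) < 4:
                raise OntologyParseError(f"line {lineno}: expected >=4 columns")
            fid, l1, l2, l3 = (f.strip() for f in fields[:4])
            if not l1:
                raise OntologyParseError(f"line {lineno}: empty level-1 category")
            name = fields[4].strip() if len(fields) > 4 else ""
            onto.add(fid, name, [(l1, l2, l3)])
    finally:
        if close:
            handle.close()
    return onto


def rollup_counts(
    counts: Mapping[str, int],
    ontology: FunctionOntology,
    level: int,
) -> dict[str, int]:
    """Sum function counts up to categories at a hierarchy level (1-3).

    Each function contributes its count at most once per category (duplicate
    same-parent affiliations are deduplicated) but contributes to every
    distinct category it belongs to at that level.  Functions missing from the
    ontology accumulate under ``unclassified``.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    out: dict[str, int] = {}
    for fid, count in counts.items():
        for cat in sorted(ontology.categories_at(fid, level)):
            out[cat] = out.get(cat, 0) + count
    return out
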