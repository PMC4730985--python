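"""Synthetic community generator with known ground truth.

Emits exactly the dialects the rest of the package reads — taxonomy TSV,
subject-metadata TSV, ontology TSV, 12-column tabular hit files and count
tables — for a community with controlled homology noise and a configurable
per-category expressed fraction, so every pipeline stage can be validated
against truth without external databases.

Randomness flows from one master seed, split per component with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .abundance import CountTable, DatasetPair
from .hits import AlignmentHit, SubjectMeta
from .ontology import FunctionOntology
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "CommunityModel",
    "GroundTruth",
    "SyntheticCatalog",
    "generate_taxonomy",
    "generate_catalog",
    "simulate_hit_table",
    "simulate_count_tables",
    "write_fixture_bundle",
]

_RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


def _rank_for_level(level: int, depth: int) -> str:
    if depth <= len(_RANKS):
        return _RANKS[level - 1]
    return _RANKS[level - 1] if level <= len(_RANKS) else f"rank_{level}"


@dataclass
class CommunityModel:
    """Abundance and activity structure of the simulated community.

    ``taxa`` maps leaf taxon ids to relative DNA abundance weights (sum 1);
    ``activity`` multiplies RNA output of a taxon's expressed genes, emulating
    taxa over- or under-represented in the metatranscriptome relative to the
    metagenome; ``expressed_fraction_per_category`` gives the probability f
    that a function in a level-1 category is expressed at all.
    """

    taxa: dict[str, float]
    activity: dict[str, float] = field(default_factory=dict)
    expressed_fraction_per_category: dict[str, float] = field(default_factory=dict)
    default_expressed_fraction: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.taxa.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"taxon abundance weights must sum to 1, got {total}")
        for cat, f in self.expressed_fraction_per_category.items():
            if not 0 <= f <= 1:
                raise ValueError(f"expressed fraction for {cat!r} must be in [0,1], got {f}")

    def f_for(self, category: str) -> float:
        return self.expressed_fraction_per_category.get(category, self.default_expressed_fraction)


@dataclass
class GroundTruth:
    """What the generator actually did, keyed the way the pipeline reports."""

    query_taxon: dict[str, str] = field(default_factory=dict)
    query_functions: dict[str, frozenset[str]] = field(default_factory=dict)
    expressed: dict[str, bool] = field(default_factory=dict)  # per function
    f_by_category: dict[str, float] = field(default_factory=dict)
    params: dict[str, object] = field(default_factory=dict)


@dataclass
class SyntheticCatalog:
    """Gene catalog: reference genes with taxon and function annotations."""

    tree: TaxonomyTree
    meta: SubjectMeta
    ontology: FunctionOntology
    gene_ids: list[str]

    def genes_of_taxon(self) -> dict[str, list[str]]:
        by_taxon: dict[str, list[str]] = {}
        for g in self.gene_ids:
            by_taxon.setdefault(self.meta.taxon[g], []).append(g)
        return by_taxon


# -- taxonomy ------------------------------------------------------------


def generate_taxonomy(
    n_leaves: int, depth: int = 6, branching: int = 3, seed: int | None = None
) -> TaxonomyTree:
    """Random rooted taxonomy with ``n_leaves`` leaves, all at ``depth``.

    Intermediate level sizes grow geometrically from the root (bounded by
    ``branching`` children per node on average); parents are assigned
    round-robin over a random permutation so every internal node has at least
    one child.  Deterministic per seed.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [1]
    for level in range(1, depth + 1):
        if level == depth:
            size = n_leaves
        else:
            # geometric interpolation root -> leaves, capped by branching
            target = max(1, round(n_leaves ** (level / depth)))
            size = min(target, sizes[-1] * branching, n_leaves)
        sizes.append(max(size, 1))
    nodes = [TaxonNode("t0", "t0", "no rank", "root")]
    level_ids: list[list[str]] = [["t0"]]
    counter = 1
    for level in range(1, depth + 1):
        ids = []
        parents = level_ids[level - 1]
        order = rng.permutation(sizes[level])
        for i in range(sizes[level]):
            tid = f"t{counter}"
            counter += 1
            parent = parents[int(order[i]) % len(parents)]
            rank = _rank_for_level(level, depth)
            nodes.append(TaxonNode(tid, parent, rank, f"{rank}_{tid}"))
            ids.append(tid)
        level_ids.append(ids)
    return TaxonomyTree(nodes)


# -- catalog -------------------------------------------------------------


def generate_catalog(
    tree: TaxonomyTree,
    n_genes: int,
    n_functions: int,
    multi_path_rate: float = 0.0,
    n_level1: int = 6,
    seed: int | None = None,
) -> SyntheticCatalog:
    """Random gene catalog over the taxonomy's leaves.

    Each function gets one (level1, level2, level3) path, plus a second
    distinct path with probability ``multi_path_rate`` (exercising the
    same-parent deduplication); each gene gets one uniformly chosen leaf taxon
    and one uniformly chosen function.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_functions < 1:
        raise ValueError("n_functions must be >= 1")
    if not 0 <= multi_path_rate <= 1:
        raise ValueError("multi_path_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    level1 = [f"L1_{i:02d}" for i in range(n_level1)]
    level2 = [f"L2_{i:02d}" for i in range(max(2 * n_level1, 4))]
    level3 = [f"L3_{i:03d}" for i in range(max(4 * n_level1, 8))]

    onto = FunctionOntology()
    fids = [f"F{i:05d}" for i in range(n_functions)]
    for i, fid in enumerate(fids):
        l1 = level1[i % n_level1]  # balanced level-1 occupancy
        path = (l1, str(rng.choice(level2)), str(rng.choice(level3)))
        paths = [path]
        if rng.random() < multi_path_rate:
            # second path; may share or differ in the level-1 parent
            alt = (str(rng.choice(level1)), str(rng.choice(level2)), str(rng.choice(level3)))
            if alt == path:
                alt = (alt[0], alt[1], level3[(level3.index(alt[2]) + 1) % len(level3)])
            paths.append(alt)
        onto.add(fid, f"protein role {fid}", paths)

    leaves = sorted(tree.leaves())
    meta = SubjectMeta()
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    taxon_choice = rng.integers(0, len(leaves), size=n_genes)
    for j, gid in enumerate(gene_ids):
        # functions assigned round-robin so every function has >=1 gene when
        # n_genes >= n_functions
        fid = fids[j % n_functions]
        meta.add(gid, leaves[int(taxon_choice[j])], [fid])
    return SyntheticCatalog(tree, meta, onto, gene_ids)


# -- hit tables ----------------------------------------------------------


def _offtarget_pool(
    catalog: SyntheticCatalog, true_taxon: str, offtarget_rank: int | str
) -> list[str]:
    """Genes whose taxon lies within the configured radius of the true taxon:
    descendants of the true leaf's ancestor ``offtarget_rank`` levels up (int)
    or at the named rank (str)."""
    tree = catalog.tree
    if isinstance(offtarget_rank, int):
        anc = true_taxon
        for _ in range(offtarget_rank):
            anc = tree.parent(anc)
    else:
        anc = tree.ancestor_at_rank(true_taxon, [offtarget_rank])
        if anc is None:
            anc = tree.root
    return [
        g for g in catalog.gene_ids if tree.is_ancestor_or_self(anc, catalog.meta.taxon[g])
    ]


def simulate_hit_table(
    catalog: SyntheticCatalog,
    queries_per_gene: int = 1,
    offtarget_prob: float = 0.0,
    offtarget_rank: int | str = 1,
    score_base: float = 120.0,
    score_noise_sd: float = 0.0,
    offtarget_penalty: float = 5.0,
    n_decoy_slots: int = 3,
    genes: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[list[AlignmentHit], GroundTruth]:
    """Simulate a homology hit table with controlled off-target noise.

    Every query gets one hit to its own source gene with bit score
    ``score_base + N(0, sd)``; each of ``n_decoy_slots`` decoy slots fires
    with probability ``offtarget_prob`` and produces a hit to a random gene
    whose taxon lies within ``offtarget_rank`` of the truth, at a score
    penalised by ``offtarget_penalty``.
    """
    if not 0 <= offtarget_prob <= 1:
        raise ValueError("offtarget_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        params={
            "queries_per_gene": queries_per_gene,
            "offtarget_prob": offtarget_prob,
            "offtarget_rank": offtarget_rank,
            "score_base": score_base,
            "score_noise_sd": score_noise_sd,
            "offtarget_penalty": offtarget_penalty,
            "n_decoy_slots": n_decoy_slots,
        }
    )
    hits: list[AlignmentHit] = []
    pool_cache: dict[str, list[str]] = {}
    source_genes = list(genes) if genes is not None else catalog.gene_ids
    qn = 0
    for gid in source_genes:
        true_taxon = catalog.meta.taxon[gid]
        for _ in range(queries_per_gene):
            qid = f"Q{qn:07d}"
            qn += 1
            truth.query_taxon[qid] = true_taxon
            truth.query_functions[qid] = catalog.meta.functions[gid]
            score = score_base + (rng.normal(0.0, score_noise_sd) if score_noise_sd else 0.0)
            hits.append(_make_hit(qid, gid, max(score, 1.0), rng))
            if offtarget_prob > 0:
                pool = pool_cache.get(true_taxon)
                if pool is None:
                    pool = _offtarget_pool(catalog, true_taxon, offtarget_rank)
                    pool_cache[true_taxon] = pool
                for _ in range(n_decoy_slots):
                    if rng.random() < offtarget_prob and pool:
                        decoy = pool[int(rng.integers(0, len(pool)))]
                        dscore = score - offtarget_penalty
                        if score_noise_sd:
                            dscore += rng.normal(0.0, score_noise_sd)
                        hits.append(_make_hit(qid, decoy, max(dscore, 1.0), rng))
    return hits, truth


def _make_hit(qid: str, sid: str, score: float, rng: np.random.Generator) -> AlignmentHit:
    length = int(rng.integers(60, 150))
    pident = float(np.round(rng.uniform(60.0, 100.0), 2))
    mismatches = int(round(length * (100.0 - pident) / 100.0))
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        percent_identity=pident,
        alignment_length=length,
        mismatches=mismatches,
        gap_opens=0,
        q_start=1,
        q_end=length,
        s_start=1,
        s_end=length,
        e_value=float(10.0 ** (-score / 10.0)),
        bit_score=float(np.round(score, 1)),
    )


# -- count tables --------------------------------------------------------


def _gene_category(catalog: SyntheticCatalog, gid: str) -> str:
    funcs = sorted(catalog.meta.functions[gid])
    if not funcs:
        return "unclassified"
    entry = catalog.ontology.entries.get(funcs[0])
    return entry.paths[0][0] if entry and entry.paths else "unclassified"


def simulate_count_tables(
    catalog: SyntheticCatalog,
    community: CommunityModel,
    total_reads_dna: int,
    total_reads_rna: int,
    seed: int | None = None,
) -> tuple[DatasetPair, GroundTruth]:
    """Paired DNA/RNA per-gene count tables with a known expressed fraction.

    DNA counts are multinomial over genes, weighted by taxon abundance split
    evenly among a taxon's genes.  Expression is a per-FUNCTION Bernoulli(f)
    indicator, f set by the function's level-1 category: the headline
    statistic counts functions, and tying the indicator to the function keeps
    the generator's f the estimand even when a function has several member
    genes.  RNA counts are multinomial over the expressed genes, weighted by
    abundance x activity.
    """
    if total_reads_dna < 0 or total_reads_rna < 0:
        raise ValueError("read totals must be >= 0")
    rng = np.random.default_rng(seed)
    genes = catalog.gene_ids
    by_taxon = catalog.genes_of_taxon()
    weights = np.zeros(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for taxon, w in community.taxa.items():
        members = by_taxon.get(taxon, [])
        for g in members:
            weights[index[g]] = w / len(members)
    if weights.sum() <= 0:
        raise ValueError("community weights select no genes")
    weights = weights / weights.sum()

    truth = GroundTruth(f_by_category=dict(community.expressed_fraction_per_category))
    # per-function expression indicator, f chosen by level-1 category of the
    # function's first path
    fn_category: dict[str, str] = {}
    for fid, entry in catalog.ontology.entries.items():
        fn_category[fid] = entry.paths[0][0] if entry.paths else "unclassified"
    for fid in sorted(catalog.ontology.entries):
        f = community.f_for(fn_category[fid])
        truth.expressed[fid] = bool(rng.random() < f)

    dna_counts = rng.multinomial(total_reads_dna, weights)

    rna_weights = np.zeros(len(genes))
    for g in genes:
        funcs = catalog.meta.functions[g]
        expressed = any(truth.expressed.get(fid, False) for fid in funcs)
        if expressed:
            act = community.activity.get(catalog.meta.taxon[g], 1.0)
            rna_weights[index[g]] = weights[index[g]] * act
    if rna_weights.sum() > 0:
        rna_weights = rna_weights / rna_weights.sum()
        rna_counts = rng.multinomial(total_reads_rna, rna_weights)
    else:
        rna_counts = np.zeros(len(genes), dtype=np.int64)

    dna = CountTable.from_counts(
        {g: int(c) for g, c in zip(genes, dna_counts) if c > 0}, "dna", "orf"
    )
    rna = CountTable.from_counts(
        {g: int(c) for g, c in zip(genes, rna_counts) if c > 0}, "rna", "orf"
    )
    truth.params = {
        "total_reads_dna": total_reads_dna,
        "total_reads_rna": total_reads_rna,
        "default_expressed_fraction": community.default_expressed_fraction,
    }
    return DatasetPair(rna=rna, dna=dna), truth


# -- fixture emission ----------------------------------------------------


def write_taxonomy_tsv(tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("taxon_id\tparent_id\trank\tname\n")
        for tid in sorted(tree.nodes, key=lambda t: (tree.depth(t), t)):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


def write_subject_meta_tsv(meta: SubjectMeta, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("subject_id\ttaxon_id\tfunction_ids\n")
        for sid in sorted(meta.taxon):
            funcs = ",".join(sorted(meta.functions.get(sid, frozenset())))
            fh.write(f"{sid}\t{meta.taxon[sid]}\t{funcs}\n")


def write_ontology_tsv(onto: FunctionOntology, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("function_id\tlevel1\tlevel2\tlevel3\tfunction_name\n")
        for fid in sorted(onto.entries):
            e = onto.entries[fid]
            for l1, l2, l3 in e.paths:
                fh.write(f"{fid}\t{l1}\t{l2}\t{l3}\t{e.name}\n")


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# dataset_id={table.dataset_id}\tunit={table.unit}\n")
        fh.write("key\tcount\n")
        for k in sorted(table.counts):
            fh.write(f"{k}\t{table.counts[k]}\n")


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("query_id\ttrue_taxon\ttrue_functions\n")
        for qid in sorted(truth.query_taxon):
            funcs = ",".join(sorted(truth.query_functions.get(qid, frozenset())))
            fh.write(f"{qid}\t{truth.query_taxon[qid]}\t{funcs}\n")


def write_fixture_bundle(
    outdir: str | Path,
    n_leaves: int = 50,
    depth: int = 6,
    branching: int = 3,
    n_genes: int = 500,
    n_functions: int = 300,
    multi_path_rate: float = 0.1,
    queries_per_gene: int = 1,
    offtarget_prob: float = 0.0,
    offtarget_rank: int | str = 1,
    score_base: float = 120.0,
    score_noise_sd: float = 0.0,
    offtarget_penalty: float = 5.0,
    total_reads_dna: int = 20000,
    total_reads_rna: int = 10000,
    expressed_fraction: float = 0.3,
    seed: int = 0,
) -> Path:
    """Emit a complete, self-consistent fixture directory.

    Contains taxonomy.tsv, subject_meta.tsv, ontology.tsv, hits.tsv,
    counts_dna.tsv, counts_rna.tsv, truth.tsv, truth_expressed.tsv and
    metadata.json echoing every generator parameter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_tax, s_cat, s_hits, s_counts = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    tree = generate_taxonomy(n_leaves, depth, branching, seed=s_tax)
    catalog = generate_catalog(tree, n_genes, n_functions, multi_path_rate, seed=s_cat)
    hits, hit_truth = simulate_hit_table(
        catalog,
        queries_per_gene=queries_per_gene,
        offtarget_prob=offtarget_prob,
        offtarget_rank=offtarget_rank,
        score_base=score_base,
        score_noise_sd=score_noise_sd,
        offtarget_penalty=offtarget_penalty,
        seed=s_hits,
    )
    leaves = sorted(tree.leaves())
    community = CommunityModel(
        taxa={t: 1.0 / len(leaves) for t in leaves},
        expressed_fraction_per_category={},
        default_expressed_fraction=expressed_fraction,
    )
    pair, count_truth = simulate_count_tables(
        catalog, community, total_reads_dna, total_reads_rna, seed=s_counts
    )

    write_taxonomy_tsv(tree, outdir / "taxonomy.tsv")
    write_subject_meta_tsv(catalog.meta, outdir / "subject_meta.tsv")
    write_ontology_tsv(catalog.ontology, outdir / "ontology.tsv")
    write_hits_tsv(hits, outdir / "hits.tsv")
    write_counts_tsv(pair.dna, outdir / "counts_dna.tsv")
    write_counts_tsv(pair.rna, outdir / "counts_rna.tsv")
    write_truth_tsv(hit_truth, outdir / "truth.tsv")
    with open(outdir / "truth_expressed.tsv", "wt", encoding="utf-8") as fh:
        fh.write("function_id\texpressed\n")
        for fid in sorted(count_truth.expressed):
            fh.write(f"{fid}\t{int(count_truth.expressed[fid])}\n")
    metadata = {
        "seed": seed,
        "component_seeds": {
            "taxonomy": s_tax,
            "catalog": s_cat,
            "hits": s_hits,
            "counts": s_counts,
        },
        "n_leaves": n_leaves,
        "depth": depth,
        "branching": branching,
        "n_genes": n_genes,
        "n_functions": n_functions,
        "multi_path_rate": multi_path_rate,
        "queries_per_gene": queries_per_gene,
        "offtarget_prob": offtarget_prob,
        "offtarget_rank": offtarget_rank,
        "score_base": score_base,
        "score_noise_sd": score_noise_sd,
        "offtarget_penalty": offtarget_penalty,
        "total_reads_dna": total_reads_dna,
        "total_reads_rna": total_reads_rna,
        "expressed_fraction": expressed_fraction,
    }
    with open(outdir / "metadata.json", "wt", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
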