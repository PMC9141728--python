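"""Exon-alignment curation and supermatrix summaries.

Individual exons approximate coalescence genes (no internal recombination),
which makes them the appropriate sequence unit for summary coalescent
methods.  This module implements the curation and bookkeeping around an
exon dataset: taxon-coverage filtering, split-codon trimming, concatenation
into partitioned nucleotide and amino-acid supermatrices,
parsimony-informative-site censuses, length statistics, short-branch
collapsing, and Robinson–Foulds comparisons of gene trees against a species
tree.  Tree inference itself is delegated to external maximum-likelihood /
quartet engines; this module prepares their inputs and consumes their
newick outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ExonError",
    "CoverageRule",
    "LAURASIATHERIA_COVERAGE",
    "ExonAlignment",
    "ExonConfig",
    "read_exon_fasta",
    "write_fasta",
    "coverage_filter",
    "trim_split_codons",
    "concatenate",
    "pi_site_count",
    "length_stats",
    "collapse_short_branches",
    "rf_distance",
]

logger = logging.getLogger(__name__)

_NT_STATES = set("ACGT")
_AA_STATES = set("ACDEFGHIKLMNPQRSTVWY")


class ExonError(ValueError):
    pass


#: Minimum per-group taxon coverage for an exon to enter the dataset.
LAURASIATHERIA_COVERAGE: dict[str, int] = {
    "Primates": 2,
    "Rodentia": 1,
    "Lagomorpha": 1,
    "Afrotheria": 2,
    "Xenarthra": 2,
    "Pholidota": 1,
    "Cetartiodactyla": 3,
    "Carnivora": 3,
    "Perissodactyla": 1,
    "Chiroptera": 5,
    "Eulipotyphla": 1,
}


@dataclass
class CoverageRule:
    """Per-group minimum counts of covered (non-empty) sequences."""

    minima: dict[str, int] = field(
        default_factory=lambda: dict(LAURASIATHERIA_COVERAGE)
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.minima.values()):
            raise ExonError("coverage minima must be >= 0")


@dataclass
class ExonAlignment:
    """One codon-complete exon alignment (nucleotide)."""

    exon_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ExonError(f"{self.exon_id}: ragged alignment")
        self.length = lengths.pop() if lengths else 0

    def translated(self) -> dict[str, str]:
        if self.length % 3:
            raise ExonError(f"{self.exon_id}: length not a multiple of 3")
        out = {}
        for taxon, seq in self.sequences.items():
            codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
            aa = []
            for c in codons:
                if "-" in c or set(c) - _NT_STATES:
                    aa.append("X" if set(c) - {"-"} else "-")
                else:
                    aa.append(str(Seq(c).translate()))
            out[taxon] = "".join(aa)
        return out


@dataclass
class ExonConfig:
    """Summary thresholds: exons strictly longer than ``min_exon_len`` form
    the long-exon subset; internal branches strictly shorter than
    ``collapse_threshold`` substitutions/site are collapsed."""

    min_exon_len: int = 500
    collapse_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.min_exon_len <= 0 or self.collapse_threshold <= 0:
            raise ExonError("thresholds must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_exon_fasta(path: str | Path, exon_id: str | None = None) -> ExonAlignment:
    path = Path(path)
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ExonError(f"{path}: no sequences")
    return ExonAlignment(exon_id or path.stem, records)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def coverage_filter(
    exon: ExonAlignment,
    rule: CoverageRule,
    group_map: dict[str, str],
) -> tuple[bool, dict[str, int]]:
    """Check the per-group coverage minima; returns (pass, tallies).

    Only non-empty sequences (at least one unambiguous residue) count as
    covering.  Adding a sequence can never flip a pass to a fail.
    """
    tallies = {g: 0 for g in rule.minima}
    for taxon, seq in exon.sequences.items():
        if taxon not in group_map:
            raise ExonError(f"{exon.exon_id}: taxon {taxon!r} not in group map")
        covered = any(c not in "-?NX" for c in seq)
        g = group_map[taxon]
        if covered and g in tallies:
            tallies[g] += 1
    ok = all(tallies[g] >= m for g, m in rule.minima.items())
    return ok, tallies


def trim_split_codons(
    exon: ExonAlignment, leading_offset: int = 0, trailing_offset: int = 0
) -> ExonAlignment | None:
    """Trim partial codons from the alignment ends.

    ``leading_offset`` / ``trailing_offset`` give the number of nucleotides
    of the split codon at each end (0 means the end is codon-complete).
    Returns the trimmed alignment, or ``None`` (logged) when nothing
    remains.
    """
    for name, off in (("leading", leading_offset), ("trailing", trailing_offset)):
        if off not in (0, 1, 2):
            raise ExonError(f"{name} offset must be 0, 1 or 2")
    new_len = exon.length - leading_offset - trailing_offset
    if new_len <= 0:
        logger.warning("%s: nothing left after split-codon trimming", exon.exon_id)
        return None
    if new_len % 3:
        raise ExonError(
            f"{exon.exon_id}: trimmed length {new_len} is not a multiple of 3; "
            "offsets are inconsistent with the alignment"
        )
    end = exon.length - trailing_offset
    return ExonAlignment(
        exon.exon_id,
        {t: s[leading_offset:end] for t, s in exon.sequences.items()},
    )


# ---------------------------------------------------------------------------
# Concatenation and site censuses
# ---------------------------------------------------------------------------

def concatenate(
    exons: list[ExonAlignment],
) -> tuple[dict[str, str], list[tuple[str, int, int]], dict[str, str]]:
    """Concatenate exons into nucleotide and amino-acid supermatrices.

    Returns ``(nt_supermatrix, partitions, aa_supermatrix)`` where
    ``partitions`` lists 1-based inclusive column ranges per exon and taxa
    absent from an exon are padded with gaps.  The amino-acid matrix always
    has exactly one third of the nucleotide columns.
    """
    ids = [e.exon_id for e in exons]
    if len(set(ids)) != len(ids):
        raise ExonError("duplicate exon ids in concatenation")
    taxa: list[str] = []
    for e in exons:
        for t in e.sequences:
            if t not in taxa:
                taxa.append(t)
    nt_parts: dict[str, list[str]] = {t: [] for t in taxa}
    aa_parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for e in exons:
        aa = e.translated()
        partitions.append((e.exon_id, pos + 1, pos + e.length))
        pos += e.length
        for t in taxa:
            nt_parts[t].append(e.sequences.get(t, "-" * e.length))
            aa_parts[t].append(aa.get(t, "-" * (e.length // 3)))
    nt = {t: "".join(p) for t, p in nt_parts.items()}
    aa = {t: "".join(p) for t, p in aa_parts.items()}
    return nt, partitions, aa


def pi_site_count(sequences: dict[str, str], alphabet: str = "nt") -> int:
    """Number of parsimony-informative columns: at least two distinct
    unambiguous states, each present in at least two sequences.  Gaps and
    ambiguity codes never count as states."""
    if not sequences:
        raise ExonError("empty alignment")
    states = _NT_STATES if alphabet == "nt" else _AA_STATES
    arr = np.array([list(s) for s in sequences.values()])
    count = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        vals, freq = np.unique(col, return_counts=True)
        keep = [f for v, f in zip(vals, freq) if v in states]
        if sum(1 for f in keep if f >= 2) >= 2:
            count += 1
    return count


def length_stats(
    lengths: list[int], threshold: int = 500
) -> dict[str, float]:
    """Median / mean / min / max of exon lengths plus the count strictly
    greater than ``threshold``."""
    if not lengths:
        raise ExonError("no exons")
    arr = np.asarray(lengths)
    return {
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "min": int(arr.min()),
        "max": int(arr.max()),
        "n_over_threshold": int((arr > threshold).sum()),
        "threshold": threshold,
        "n": len(lengths),
    }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _as_tree(tree, namespace=None) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree, schema="newick", taxon_namespace=namespace
    )


def collapse_short_branches(tree, threshold: float = 0.01) -> dendropy.Tree:
    """Contract internal edges strictly shorter than ``threshold``
    substitutions/site into polytomies; leaf edges are never touched."""
    t = _as_tree(tree).clone(depth=1)
    to_collapse = []
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node or edge.head_node.is_leaf():
            continue
        if edge.length is None:
            raise ExonError("tree has internal edges without branch lengths")
        if edge.length < threshold:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return t


def rf_distance(tree1, tree2, prune_to_shared: bool = True) -> int:
    """Unweighted Robinson–Foulds distance: the size of the symmetric
    difference of the two trees' nontrivial bipartition sets on the shared
    leaf set (trees are compared unrooted)."""
    ns = dendropy.TaxonNamespace()
    t1 = _as_tree(tree1, ns).clone(depth=1)
    t2 = _as_tree(tree2, ns).clone(depth=1)
    labels1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    labels2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    shared = labels1 & labels2
    if len(shared) < 4:
        raise ExonError(
            f"only {len(shared)} shared taxa; Robinson-Foulds needs >= 4"
        )
    if prune_to_shared:
        if labels1 - shared:
            t1.retain_taxa_with_labels(sorted(shared))
        if labels2 - shared:
            t2.retain_taxa_with_labels(sorted(shared))
    elif labels1 != labels2:
        raise ExonError("taxon sets differ; enable prune_to_shared")
    t1.migrate_taxon_namespace(ns)
    t2.migrate_taxon_namespace(ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
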