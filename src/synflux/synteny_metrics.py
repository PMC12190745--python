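"""Pairwise gene-content and gene-order comparison.

Two statistics are computed for every unordered pair of genomes in a
clade:

* the **gene content distance** (GCD), the log-corrected fraction of
  shared ortholog clusters, d_AB = -ln(N_AB / sqrt(N_A * N_B)), which
  approximates the number of gene gains plus losses per gene at short
  evolutionary distances, and
* the **syntenic block length (SBL) distribution**: after reducing both
  genomes to their shared single-copy gene complement, maximal runs of
  genes whose adjacencies are conserved between the two genomes are
  identified (orientation-blind, degenerate length-1 blocks included)
  and their lengths tallied.

The SBL distribution is the empirical object later fitted by the jump
model; the mean SBL ranges from the genome length (identical gene
orders, one block) down to 1 (fully scrambled).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import CladeDataset, Genome, Replicon

__all__ = [
    "GeneContentSummary",
    "SBLDistribution",
    "PairComparison",
    "gene_content_distance",
    "common_complement",
    "extract_synteny_blocks",
    "mean_sbl",
    "compare_all_pairs",
    "write_pair_table",
]


@dataclass(frozen=True)
class GeneContentSummary:
    """Distinct ortholog-cluster counts for a genome pair (N_A, N_B, N_AB)."""

    n_a: int
    n_b: int
    n_shared: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= min(self.n_a, self.n_b)):
            raise ValueError("n_shared must lie in [0, min(n_a, n_b)]")


@dataclass(frozen=True)
class SBLDistribution:
    """Counts of syntenic block lengths for one genome pair."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(k < 1 or c < 0 for k, c in self.counts.items()):
            raise ValueError("block lengths must be >= 1 and counts >= 0")

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "SBLDistribution":
        return cls(dict(Counter(int(x) for x in lengths)))

    @property
    def total_blocks(self) -> int:
        return sum(self.counts.values())

    @property
    def total_genes(self) -> int:
        return sum(k * c for k, c in self.counts.items())

    @property
    def pmf(self) -> dict[int, float]:
        n = self.total_blocks
        return {k: c / n for k, c in sorted(self.counts.items())}

    def support_cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct lengths (ascending) and the empirical CDF at each."""
        ks = np.array(sorted(self.counts), dtype=np.int64)
        w = np.array([self.counts[int(k)] for k in ks], dtype=float)
        return ks, np.cumsum(w) / w.sum()


@dataclass(frozen=True)
class PairComparison:
    """GCD plus SBL distribution for one unordered genome pair."""

    genome_a: str
    genome_b: str
    summary: GeneContentSummary
    gcd: float
    sbl: SBLDistribution | None
    mean_sbl: float | None
    usable: bool = True
    reason: str = ""


def gene_content_distance(a: Genome, b: Genome) -> tuple[GeneContentSummary, float]:
    """GCD between two genomes: -ln(N_AB / sqrt(N_A * N_B)).

    Distinct ortholog clusters are counted once regardless of copy number
    (paralogy is ignored).  Raises ValueError if the genomes share no
    clusters, where the distance is undefined (infinite).
    """
    set_a = set(a.cog_multiset)
    set_b = set(b.cog_multiset)
    shared = set_a & set_b
    summary = GeneContentSummary(len(set_a), len(set_b), len(shared))
    if not shared:
        raise ValueError(
            f"genomes {a.genome_id!r} and {b.genome_id!r} share no ortholog clusters; "
            "gene content distance is undefined"
        )
    gcd = -math.log(summary.n_shared / math.sqrt(summary.n_a * summary.n_b))
    return summary, max(gcd, 0.0)


def _single_copy_shared(a: Genome, b: Genome) -> set[str]:
    ma, mb = a.cog_multiset, b.cog_multiset
    return {c for c in ma.keys() & mb.keys() if ma[c] == 1 and mb[c] == 1}


def common_complement(a: Genome, b: Genome) -> tuple[Genome, Genome]:
    """Reduce both genomes to their shared single-copy gene complement.

    Genes whose ortholog cluster is absent from the other genome are
    dropped, as are clusters with copy number > 1 in either genome:
    multi-copy clusters make adjacency conservation ill-defined, and
    paralogy is outside the comparison's scope.  Relative gene order
    within each replicon is preserved; replicons left empty are dropped.
    """
    keep = _single_copy_shared(a, b)
    if not keep:
        raise ValueError(
            f"genomes {a.genome_id!r} and {b.genome_id!r} have no shared single-copy genes"
        )

    def reduce(g: Genome) -> Genome:
        reps = []
        for rep in g.replicons:
            genes = tuple((c, s) for c, s in rep.genes if c in keep)
            if genes:
                reps.append(Replicon(rep.replicon_id, rep.topology, genes))
        return Genome(g.genome_id, tuple(reps))

    return reduce(a), reduce(b)


def _adjacency_set(g: Genome) -> set[frozenset]:
    adj: set[frozenset] = set()
    for rep in g.replicons:
        cogs = rep.cog_ids
        m = len(cogs)
        for i in range(m - 1):
            adj.add(frozenset((cogs[i], cogs[i + 1])))
        if rep.topology == "circular" and m >= 3:
            adj.add(frozenset((cogs[-1], cogs[0])))
    return adj


def _replicon_block_lengths(rep: Replicon, other_adj: set[frozenset]) -> list[int]:
    cogs = rep.cog_ids
    m = len(cogs)
    if m == 1:
        return [1]
    conserved = [frozenset((cogs[i], cogs[i + 1])) in other_adj for i in range(m - 1)]
    wrap = rep.topology == "circular" and frozenset((cogs[-1], cogs[0])) in other_adj
    if all(conserved) and (wrap or rep.topology == "linear"):
        return [m]
    # split into runs at broken adjacencies
    lengths, run = [], 1
    for ok in conserved:
        if ok:
            run += 1
        else:
            lengths.append(run)
            run = 1
    lengths.append(run)
    if wrap and len(lengths) > 1:
        # block crossing the origin of a circular replicon is one block
        lengths[0] += lengths.pop()
    return lengths


def extract_synteny_blocks(reduced_a: Genome, reduced_b: Genome) -> SBLDistribution:
    """Tally syntenic block lengths between two reduced genomes.

    A block is a maximal run of consecutive genes in A such that every
    internal adjacency of the run is also an adjacency in B.  Adjacency
    is an unordered pair of ortholog clusters occupying neighboring
    positions on the same replicon (so a run matching B in reversed
    orientation still counts, and on circular replicons the last-first
    pair is an adjacency).  Blocks never span replicon boundaries.
    Inputs must come from :func:`common_complement` (single-copy shared
    genes only).
    """
    adj_b = _adjacency_set(reduced_b)
    lengths: list[int] = []
    for rep in reduced_a.replicons:
        lengths.extend(_replicon_block_lengths(rep, adj_b))
    return SBLDistribution.from_lengths(lengths)


def mean_sbl(sbl: SBLDistribution) -> float:
    """Mean syntenic block length, sum(k * counts[k]) / total blocks."""
    n = sbl.total_blocks
    if n == 0:
        raise ValueError("empty SBL distribution")
    return sbl.total_genes / n


def compare_pair(a: Genome, b: Genome) -> PairComparison:
    """Full comparison for one genome pair; failures are flagged, not raised."""
    try:
        summary, gcd = gene_content_distance(a, b)
    except ValueError:
        set_a, set_b = set(a.cog_multiset), set(b.cog_multiset)
        summary = GeneContentSummary(len(set_a), len(set_b), 0)
        return PairComparison(a.genome_id, b.genome_id, summary, math.inf, None, None,
                              usable=False, reason="no shared ortholog clusters")
    try:
        ra, rb = common_complement(a, b)
    except ValueError:
        return PairComparison(a.genome_id, b.genome_id, summary, gcd, None, None,
                              usable=False, reason="no shared single-copy genes")
    sbl = extract_synteny_blocks(ra, rb)
    msbl = mean_sbl(sbl)
    if gcd == 0.0:
        # identical gene content: q*d degenerates, pair cannot constrain the fit
        return PairComparison(a.genome_id, b.genome_id, summary, gcd, sbl, msbl,
                              usable=False, reason="identical gene content (gcd = 0)")
    return PairComparison(a.genome_id, b.genome_id, summary, gcd, sbl, msbl)


def compare_all_pairs(dataset: CladeDataset) -> list[PairComparison]:
    """One :class:`PairComparison` per unordered genome pair in the clade."""
    return [
        compare_pair(a, b)
        for a, b in itertools.combinations(dataset.genomes, 2)
    ]


def write_pair_table(
    clade_id: str,
    pairs: Sequence[PairComparison],
    path: str | Path,
    sbl_dir: str | Path | None = None,
) -> None:
    """Export pair comparisons as TSV, optionally with per-pair SBL histograms."""
    rows = []
    for p in pairs:
        rows.append({
            "clade_id": clade_id,
            "genome_a": p.genome_a,
            "genome_b": p.genome_b,
            "n_a": p.summary.n_a,
            "n_b": p.summary.n_b,
            "n_shared": p.summary.n_shared,
            "gcd": p.gcd,
            "n_blocks": p.sbl.total_blocks if p.sbl else 0,
            "mean_sbl": p.mean_sbl if p.mean_sbl is not None else float("nan"),
            "usable": p.usable,
            "reason": p.reason,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if sbl_dir is not None:
        sbl_dir = Path(sbl_dir)
        sbl_dir.mkdir(parents=True, exist_ok=True)
        for p in pairs:
            if p.sbl is None:
                continue
            hist = pd.DataFrame(sorted(p.sbl.counts.items()), columns=["k", "count"])
            hist.to_csv(sbl_dir / f"{clade_id}.{p.genome_a}.{p.genome_b}.sbl.tsv",
                        sep="\t", index=False)
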