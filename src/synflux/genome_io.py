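"""Reading, validation and preprocessing of gene-order tables.

A clade (an ATGC-like group of closely related genomes) is supplied as a
TSV file with one row per gene and columns::

    genome_id  replicon_id  topology  position  strand  cog_id

``topology`` is ``circular`` or ``linear`` and must be constant within a
replicon; ``position`` is a 0-based, gapless index along the replicon;
``cog_id`` is the ortholog-cluster label used to match genes across
genomes.  Ortholog assignment itself is taken as given (as in the ATGC
resource) — this module never parses sequence annotation.

Preprocessing follows the study's genome-selection rules: groups of
genomes with identical ortholog-cluster content are collapsed to a single
representative (:func:`reduce_cliques`), and only clades with at least
``min_genomes`` genomes are analyzed (:func:`filter_clades`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "TOPOLOGIES",
    "STRANDS",
    "REQUIRED_COLUMNS",
    "FormatError",
    "ValidationError",
    "GeneRecord",
    "Replicon",
    "Genome",
    "CladeDataset",
    "read_gene_order_table",
    "write_gene_order_table",
    "read_clade_directory",
    "reduce_cliques",
    "filter_clades",
]

TOPOLOGIES = ("circular", "linear")
STRANDS = ("+", "-")
REQUIRED_COLUMNS = ["genome_id", "replicon_id", "topology", "position", "strand", "cog_id"]


class FormatError(ValueError):
    """The input table violates the TSV dialect (columns, tokens, types)."""


class ValidationError(ValueError):
    """The table parses but violates a dataset invariant (e.g. position gaps)."""


class GeneRecord(NamedTuple):
    genome_id: str
    replicon_id: str
    topology: str
    position: int
    strand: str
    cog_id: str


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid: an ordered list of (cog_id, strand) genes."""

    replicon_id: str
    topology: str
    genes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise FormatError(f"unknown topology {self.topology!r} on replicon {self.replicon_id!r}")

    @property
    def cog_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Genome:
    """Ordered ortholog-cluster labels of one genome, grouped by replicon."""

    genome_id: str
    replicons: tuple[Replicon, ...]

    def __post_init__(self) -> None:
        if not self.replicons or all(len(r) == 0 for r in self.replicons):
            raise ValidationError(f"genome {self.genome_id!r} has no genes")

    @property
    def cog_multiset(self) -> Counter:
        return Counter(c for r in self.replicons for c in r.cog_ids)

    @property
    def n_genes(self) -> int:
        return sum(len(r) for r in self.replicons)

    def records(self) -> list[GeneRecord]:
        out = []
        for rep in self.replicons:
            for pos, (cog, strand) in enumerate(rep.genes):
                out.append(GeneRecord(self.genome_id, rep.replicon_id, rep.topology, pos, strand, cog))
        return out


@dataclass
class CladeDataset:
    clade_id: str
    genomes: list[Genome]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate genome ids in clade {self.clade_id!r}")

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


def _genome_from_frame(genome_id: str, df: pd.DataFrame) -> Genome:
    replicons = []
    for rep_id in df["replicon_id"].drop_duplicates():
        sub = df[df["replicon_id"] == rep_id]
        topos = sub["topology"].unique()
        if len(topos) > 1:
            raise ValidationError(
                f"replicon {rep_id!r} of genome {genome_id!r} has inconsistent topology {sorted(topos)}"
            )
        if topos[0] not in TOPOLOGIES:
            raise FormatError(f"unknown topology token {topos[0]!r} (expected one of {TOPOLOGIES})")
        bad = set(sub["strand"]) - set(STRANDS)
        if bad:
            raise FormatError(f"unknown strand token(s) {sorted(bad)} (expected one of {STRANDS})")
        positions = sorted(int(p) for p in sub["position"])
        if positions != list(range(len(sub))):
            raise ValidationError(
                f"positions on replicon {rep_id!r} of genome {genome_id!r} are not a gapless "
                f"0..{len(sub) - 1} sequence"
            )
        ordered = sub.sort_values("position")
        genes = tuple(zip(ordered["cog_id"].astype(str), ordered["strand"]))
        replicons.append(Replicon(str(rep_id), str(topos[0]), genes))
    return Genome(str(genome_id), tuple(replicons))


def read_gene_order_table(path: str | Path, clade_id: str | None = None) -> CladeDataset:
    """Read one clade's gene-order TSV into a validated :class:`CladeDataset`.

    Genomes and replicons keep their order of first appearance in the file;
    genes are sorted by position within each replicon.
    """
    path = Path(path)
    if clade_id is None:
        clade_id = path.stem
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["position"] = df["position"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer position value") from exc
    if (df["position"] < 0).any():
        raise ValidationError(f"{path}: negative position value")
    genomes = [
        _genome_from_frame(gid, df[df["genome_id"] == gid])
        for gid in df["genome_id"].drop_duplicates()
    ]
    return CladeDataset(clade_id, genomes, provenance=f"read from {path.name}")


def write_gene_order_table(dataset: CladeDataset, path: str | Path) -> None:
    rows = [rec for g in dataset.genomes for rec in g.records()]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clade_directory(path: str | Path, pattern: str = "*.tsv") -> list[CladeDataset]:
    """Read every clade TSV in a directory (clade_id = file stem)."""
    files = sorted(Path(path).glob(pattern))
    return [read_gene_order_table(f) for f in files]


def reduce_cliques(dataset: CladeDataset) -> CladeDataset:
    """Collapse genomes with identical ortholog-cluster multisets.

    Pairs with identical gene content have gene content distance 0, which
    would degenerate the downstream model fit (the predicted translocation
    load q*d would be 0 regardless of q); each clique of content-identical
    genomes is therefore reduced to its lexicographically smallest
    genome_id.  Input order is otherwise preserved, and the operation is
    idempotent.
    """
    groups: dict[frozenset, str] = {}
    for g in dataset.genomes:
        key = frozenset(g.cog_multiset.items())
        if key not in groups or g.genome_id < groups[key]:
            groups[key] = g.genome_id
    keep = set(groups.values())
    kept = [g for g in dataset.genomes if g.genome_id in keep]
    return CladeDataset(dataset.clade_id, kept, dataset.provenance)


def filter_clades(
    datasets: Iterable[CladeDataset],
    min_genomes: int = 3,
    exclude_ids: Sequence[str] = (),
) -> list[CladeDataset]:
    """Keep clades with >= min_genomes genomes whose id is not excluded."""
    excluded = set(exclude_ids)
    return [
        ds for ds in datasets
        if ds.n_genomes >= min_genomes and ds.clade_id not in excluded
    ]
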