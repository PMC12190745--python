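"""Synthetic clade generator with known rearrangement-to-flux ratio.

Emulates the statistical structure the analysis assumes: an ancestral
genome of unique ortholog clusters on one circular (or linear) replicon,
evolved independently along a star tree.  Each branch applies balanced
gene losses and gains (gains are brand-new clusters, never re-gained)
and single-gene translocations, with the per-branch translocation count
tied to the flux count through the ground-truth ratio q_true, so that
every genome pair satisfies lambda = q_true * d in expectation.
Segmental inversions can be added as an out-of-model confounder (they
are never fitted; their only role is to inflate the residual misfit of
the jump model, the deviation attributed to segmental events).

A companion generator produces ortholog-presence matrices with
clade-level q values for calibrating the correlation screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import CladeDataset, Genome, Replicon

__all__ = [
    "SyntheticParams",
    "CladeTruth",
    "make_ancestor",
    "evolve_branch",
    "make_clade",
    "make_presence_matrix",
    "write_truth",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for one synthetic clade.

    d_range is the target interval for *pairwise* gene content distances;
    per-branch depths are drawn uniformly from [d_lo/2, d_hi/2] so every
    pair's expected GCD lands inside d_range.  inversion_rate is the
    number of segmental inversions per gain-loss pair on a branch
    (confounder, 0 under the pure model).
    """

    n_genes: int = 3000
    n_genomes: int = 6
    q_true: float = 0.1
    d_range: tuple[float, float] = (0.02, 0.1)
    topology: str = "circular"
    inversion_rate: float = 0.0
    seed: int = 0
    clade_id: str = "SYN"

    def __post_init__(self) -> None:
        lo, hi = self.d_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("d_range must lie within (0, 0.5]")
        if self.n_genomes < 3:
            raise ValueError("a clade needs >= 3 genomes")
        if self.q_true <= 0.0:
            raise ValueError("q_true must be positive")
        if self.n_genes < 500:
            raise ValueError("n_genes >= 500 required for model-regime validity")


@dataclass(frozen=True)
class CladeTruth:
    """Ground truth recorded alongside a generated clade."""

    q_true: float
    seed: int
    branch_losses: tuple[int, ...]
    branch_gains: tuple[int, ...]
    branch_jumps: tuple[int, ...]
    branch_inversions: tuple[int, ...]


def make_ancestor(n_genes: int, topology: str = "circular", seed: int = 0) -> Genome:
    """Ancestral genome: one replicon of n_genes unique ortholog clusters."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    genes = tuple((f"g{i:06d}", "+" if i % 2 == 0 else "-") for i in range(n_genes))
    return Genome("ancestor", (Replicon("r1", topology, genes),))


def _invert_segment(genes: list, start: int, length: int, circular: bool) -> None:
    """Reverse a gene segment in place, flipping strands; wraps if circular."""
    m = len(genes)
    length = min(length, m)
    if circular:
        idx = [(start + i) % m for i in range(length)]
        seg = [genes[i] for i in idx]
        for i, (cog, strand) in zip(idx, reversed(seg)):
            genes[i] = (cog, "-" if strand == "+" else "+")
    else:
        end = min(start + length, m)
        seg = genes[start:end]
        genes[start:end] = [(c, "-" if s == "+" else "+") for c, s in reversed(seg)]


def evolve_branch(
    g: Genome,
    n_loss: int,
    n_gain: int,
    n_jumps: int,
    n_inversions: int = 0,
    seed: int = 0,
    gain_prefix: str = "new",
    genome_id: str | None = None,
    inversion_mean_len: float = 5.0,
) -> Genome:
    """Apply losses, gains, jumps and inversions in uniformly shuffled order.

    Losses delete uniformly chosen genes; gains insert brand-new unique
    clusters (label ``{gain_prefix}{i:06d}``) at uniform positions; jumps
    excise and reinsert a uniformly chosen gene; inversions reverse a
    uniformly placed segment of geometric length (mean
    ``inversion_mean_len``, operon scale).  Single-replicon genomes only.
    """
    if len(g.replicons) != 1:
        raise ValueError("evolve_branch expects a single-replicon genome")
    rep = g.replicons[0]
    if n_loss >= len(rep):
        raise ValueError(f"n_loss={n_loss} must be smaller than genome size {len(rep)}")
    rng = np.random.default_rng(seed)
    events = ["L"] * n_loss + ["G"] * n_gain + ["J"] * n_jumps + ["I"] * n_inversions
    rng.shuffle(events)
    genes = list(rep.genes)
    circular = rep.topology == "circular"
    gained = 0
    for ev in events:
        m = len(genes)
        if ev == "L":
            genes.pop(int(rng.integers(m)))
        elif ev == "G":
            label = f"{gain_prefix}{gained:06d}"
            gained += 1
            genes.insert(int(rng.integers(m + 1)), (label, "+"))
        elif ev == "J":
            gene = genes.pop(int(rng.integers(m)))
            genes.insert(int(rng.integers(m)), gene)
        else:  # inversion
            start = int(rng.integers(m))
            length = int(rng.geometric(1.0 / inversion_mean_len))
            _invert_segment(genes, start, max(2, length), circular)
    return Genome(
        genome_id or g.genome_id,
        (Replicon(rep.replicon_id, rep.topology, tuple(genes)),),
    )


def make_clade(params: SyntheticParams) -> tuple[CladeDataset, CladeTruth]:
    """Generate one clade: the ancestor evolved along a star tree.

    Branch depths delta_i ~ U[d_lo/2, d_hi/2] (in GCD units) give each
    branch L_i = round(delta_i * n) balanced loss-gain pairs and
    J_i = round(q_true * L_i) translocations, so a pair (i, j) has
    expected GCD delta_i + delta_j inside d_range and translocation load
    lambda_ij = (J_i + J_j)/n = q_true * d_ij.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    half_lo, half_hi = p.d_range[0] / 2.0, p.d_range[1] / 2.0
    if round(half_hi * p.n_genes) >= p.n_genes // 2:
        raise ValueError(f"d_range {p.d_range} infeasible for n_genes={p.n_genes}")
    if round(half_lo * p.n_genes) < 1:
        raise ValueError(f"d_range {p.d_range} too small to realize one event at n_genes={p.n_genes}")
    ancestor = make_ancestor(p.n_genes, p.topology, seed=int(rng.integers(2**31)))
    depths = rng.uniform(half_lo, half_hi, size=p.n_genomes)
    losses, gains, jumps, invs, genomes = [], [], [], [], []
    for i, delta in enumerate(depths):
        L = max(1, round(float(delta) * p.n_genes))
        J = round(p.q_true * L)
        V = round(p.inversion_rate * L)
        branch_seed = int(rng.integers(2**31))
        genomes.append(
            evolve_branch(
                ancestor, L, L, J, V,
                seed=branch_seed,
                gain_prefix=f"n{i}_",
                genome_id=f"G{i:02d}",
            )
        )
        losses.append(L); gains.append(L); jumps.append(J); invs.append(V)
    dataset = CladeDataset(
        p.clade_id, genomes,
        provenance=f"synthetic star clade, q_true={p.q_true}, seed={p.seed}",
    )
    truth = CladeTruth(p.q_true, p.seed, tuple(losses), tuple(gains), tuple(jumps), tuple(invs))
    return dataset, truth


def write_truth(truth: CladeTruth, path: str | Path) -> None:
    """Plain-text key=value sidecar recording the generating parameters."""
    with open(path, "w") as fh:
        fh.write(f"q_true={truth.q_true}\n")
        fh.write(f"seed={truth.seed}\n")
        for name in ("branch_losses", "branch_gains", "branch_jumps", "branch_inversions"):
            fh.write(f"{name}={','.join(str(x) for x in getattr(truth, name))}\n")


def make_presence_matrix(
    n_clades: int,
    n_cogs: int,
    effect_cog: int | None = None,
    effect_factor: float = 4.0,
    seed: int = 0,
    q_median: float = 0.13,
    q_sigma: float = 0.8,
    fractional_prob: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Presence fractions (clades x cogs) plus per-clade q values.

    Presence is mostly binary: each cog has a baseline prevalence drawn
    uniformly, each clade is present/absent by a Bernoulli draw, and a
    small fraction of entries is replaced by an intermediate fraction
    (a cog present in only part of the clade's genomes).  q values are
    log-normal (median ``q_median``, log-sd ``q_sigma``, matching the
    order-of-magnitude spread seen across real clades); when
    ``effect_cog`` is set, clades where that cog is present have q
    multiplied by ``effect_factor`` (the alternative hypothesis for
    screen power checks).
    """
    if n_clades < 10:
        raise ValueError("n_clades must be >= 10")
    rng = np.random.default_rng(seed)
    prevalence = rng.uniform(0.1, 0.9, size=n_cogs)
    presence = (rng.random((n_clades, n_cogs)) < prevalence).astype(float)
    frac_mask = rng.random((n_clades, n_cogs)) < fractional_prob
    presence[frac_mask] = rng.random(int(frac_mask.sum()))
    q = np.exp(rng.normal(math.log(q_median), q_sigma, size=n_clades))
    if effect_cog is not None:
        q = q * np.where(presence[:, effect_cog] > 0.5, effect_factor, 1.0)
    return presence, q
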