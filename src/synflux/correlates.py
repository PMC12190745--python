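"""Correlation analyses around the fitted ratios.

Two in-scope analyses: the association between gene content distance and
mean syntenic block length across genome pairs (a strong negative rank
correlation is expected, since flux and rearrangement accumulate on the
same pairwise timescale), and a permutation screen asking whether the
presence of any individual ortholog cluster across clades predicts the
clade's rearrangement-to-flux ratio.  The screen calls a cog significant
only when the rank correlation is both strong (|rho| >= r_threshold)
and robust under permutations (p <= p_threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .synteny_metrics import PairComparison

__all__ = ["ScreenResult", "gcd_sbl_correlation", "cog_presence_screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    cog_index: int
    rho: float
    p_perm: float
    significant: bool


def gcd_sbl_correlation(pairs: Sequence[PairComparison]) -> float:
    """Spearman rank correlation between GCD and mean SBL over genome pairs.

    Pairs without a defined mean SBL or with infinite GCD are ignored;
    at least 3 informative pairs are required, and a constant vector
    (undefined correlation) raises.
    """
    xs = [p.gcd for p in pairs if p.mean_sbl is not None and math.isfinite(p.gcd)]
    ys = [p.mean_sbl for p in pairs if p.mean_sbl is not None and math.isfinite(p.gcd)]
    if len(xs) < 3:
        raise ValueError(f"need >= 3 informative pairs, got {len(xs)}")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("correlation undefined: constant GCD or mean SBL vector")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def cog_presence_screen(
    presence: np.ndarray,
    q_values: np.ndarray,
    n_perm: int = 10_000,
    r_threshold: float = 0.4,
    p_threshold: float = 0.001,
    seed: int = 0,
) -> list[ScreenResult]:
    """Permutation screen of ortholog presence against per-clade q values.

    For each cog (column of ``presence``, clades x cogs), the Spearman
    correlation between its presence-fraction vector and ``q_values`` is
    computed; its permutation p-value is the add-one estimator
    (1 + #{permuted |rho| >= observed |rho|}) / (n_perm + 1), two-sided,
    obtained by shuffling the q values.  Constant presence columns have
    an undefined correlation and are skipped with a warning.  Seeded and
    invariant to cog column order.
    """
    presence = np.asarray(presence, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    if presence.ndim != 2 or presence.shape[0] != q_values.shape[0]:
        raise ValueError(
            f"presence has {presence.shape} rows but q_values has length {len(q_values)}"
        )
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    n_clades, n_cogs = presence.shape

    keep = [j for j in range(n_cogs) if not np.allclose(presence[:, j], presence[0, j])]
    skipped = sorted(set(range(n_cogs)) - set(keep))
    if skipped:
        logger.warning("skipping %d constant presence column(s): %s", len(skipped), skipped)
    if not keep:
        return []

    # Spearman = Pearson on mid-ranked data; permutation shuffles the q ranks.
    pres_rank = np.apply_along_axis(stats.rankdata, 0, presence[:, keep])
    q_rank = stats.rankdata(q_values)
    pz = (pres_rank - pres_rank.mean(axis=0)) / pres_rank.std(axis=0)
    qz = (q_rank - q_rank.mean()) / q_rank.std()
    rho_obs = pz.T @ qz / n_clades

    rng = np.random.default_rng(seed)
    perms = np.empty((n_clades, n_perm))
    for t in range(n_perm):
        perms[:, t] = rng.permutation(qz)
    rho_perm = np.abs(pz.T @ perms / n_clades)  # (n_kept, n_perm)
    exceed = (rho_perm >= np.abs(rho_obs)[:, None]).sum(axis=1)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    results = []
    for idx, j in enumerate(keep):
        rho = float(rho_obs[idx])
        p = float(p_perm[idx])
        results.append(ScreenResult(j, rho, p, bool(abs(rho) >= r_threshold and p <= p_threshold)))
    return results
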