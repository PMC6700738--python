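"""geNorm expression-stability analysis.

The geNorm statistic for gene *j* within an active candidate set *A* is

    M_j = mean over k in A, k != j, of V_jk
    V_jk = sd over samples of log2( q_j / q_k )        (n-1 denominator)

Because V is built from within-sample ratios, any per-sample loading
effect cancels, and multiplying a gene's quantity vector by a positive
constant changes nothing.  Genes are excluded one at a time — always the
one with the highest M, recomputing M within the shrinking set — until
two remain.  Those two cannot be separated by the statistic (their final
M values are identical by construction) and share rank 1; the remaining
genes take ranks 3, 4, ... in reverse exclusion order.

A gene whose first-pass M exceeds the conventional threshold of 1.5 is
flagged as unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refstab.preprocess import QMatrix

logger = logging.getLogger(__name__)

#: Conventional M-value cutoff above which a candidate is called unstable.
DEFAULT_M_THRESHOLD = 1.5


@dataclass
class GeNormResult:
    """Outcome of the iterative geNorm ranking.

    Attributes
    ----------
    m_initial
        First-pass M per gene, computed with every candidate active.
    m_final
        M value of each gene at the step it was excluded (for the two
        survivors: their M in the final pair).
    ranks
        Competition ranks: the two survivors share rank 1, then 3, 4, ...
    exclusion_order
        Genes from least stable (first removed) to most stable; length
        ``n_genes - 2``.
    m_trace
        One dict per iteration mapping each then-active gene to its M.
    flagged_unstable
        Genes with first-pass M above the threshold.
    """

    m_initial: pd.Series
    m_final: pd.Series
    ranks: pd.Series
    exclusion_order: list[str]
    m_trace: list[dict[str, float]]
    flagged_unstable: list[str]
    threshold: float = DEFAULT_M_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.m_initial.index,
                "m_initial": self.m_initial.values,
                "m_final": self.m_final[self.m_initial.index].values,
                "rank": self.ranks[self.m_initial.index].values,
                "flagged_unstable": [
                    g in self.flagged_unstable for g in self.m_initial.index
                ],
            }
        )


def pairwise_variation(q_j, q_k) -> float:
    """Standard deviation of per-sample log2 ratios between two genes.

    Both vectors must be complete, positive and of equal length >= 2.
    Symmetric in its arguments and invariant to scaling either vector
    by a positive constant.
    """
    q_j = np.asarray(q_j, dtype=float)
    q_k = np.asarray(q_k, dtype=float)
    if q_j.shape != q_k.shape or q_j.ndim != 1 or q_j.size < 2:
        raise ValueError("pairwise_variation needs equal-length vectors, n >= 2")
    if (q_j <= 0).any() or (q_k <= 0).any():
        raise ValueError("pairwise_variation: quantities must be positive")
    ratios = np.log2(q_j / q_k)
    return float(np.std(ratios, ddof=1))


def _m_values(log2q: pd.DataFrame, active: list[str]) -> pd.Series:
    """M for every gene in `active`, via the pairwise log-ratio SD matrix."""
    sub = log2q.loc[active].to_numpy()
    n = sub.shape[1]
    # V_jk = sd(l_j - l_k), computed from per-sample log-quantity differences
    diffs = sub[:, None, :] - sub[None, :, :]
    mean = diffs.mean(axis=2, keepdims=True)
    v = np.sqrt(((diffs - mean) ** 2).sum(axis=2) / (n - 1))
    k = len(active)
    m = v.sum(axis=1) / (k - 1)
    return pd.Series(m, index=active)


def m_value(q: QMatrix, gene: str, active: list[str]) -> float:
    """geNorm M of one gene within an active candidate subset."""
    if gene not in active:
        raise ValueError(f"gene {gene!r} not in the active set")
    if len(active) < 2:
        raise ValueError("m_value needs at least 2 active genes")
    return float(_m_values(q.log2(), list(active))[gene])


def genorm_rank(q: QMatrix, threshold: float = DEFAULT_M_THRESHOLD) -> GeNormResult:
    """Iterative geNorm ranking of all genes in a Q matrix.

    Requires at least 3 complete genes.  Ties in "highest M" during
    exclusion are broken by input gene order (first tied gene removed),
    which is logged when it happens.
    """
    genes = q.gene_ids
    if len(genes) < 3:
        raise ValueError(f"genorm_rank needs >= 3 genes, got {len(genes)}")
    log2q = q.log2()

    active = list(genes)
    m_initial = _m_values(log2q, active)
    flagged = [g for g in genes if m_initial[g] > threshold]

    m_final = pd.Series(np.nan, index=genes)
    exclusion_order: list[str] = []
    m_trace: list[dict[str, float]] = []
    while len(active) > 2:
        m = _m_values(log2q, active)
        m_trace.append(m.to_dict())
        worst_val = m.max()
        tied = [g for g in active if m[g] == worst_val]
        if len(tied) > 1:
            logger.info("genorm: M tie among %s, removing %r (input order)", tied, tied[0])
        worst = tied[0]
        m_final[worst] = m[worst]
        active.remove(worst)
        exclusion_order.append(worst)
    final_pair_m = _m_values(log2q, active)
    m_trace.append(final_pair_m.to_dict())
    for g in active:
        m_final[g] = final_pair_m[g]

    ranks = pd.Series(0, index=genes, dtype=int)
    for g in active:
        ranks[g] = 1
    # last excluded is third most stable
    for pos, g in enumerate(reversed(exclusion_order), start=3):
        ranks[g] = pos
    return GeNormResult(
        m_initial=m_initial.reindex(genes),
        m_final=m_final,
        ranks=ranks,
        exclusion_order=exclusion_order,
        m_trace=m_trace,
        flagged_unstable=flagged,
        threshold=threshold,
    )


def normalization_factor_variation(q: QMatrix, max_genes: int | None = None) -> pd.DataFrame:
    """Optional V(n/n+1) diagnostic for choosing how many reference genes.

    V_n is the sd of per-sample log2 ratios between the geometric-mean
    normalization factors built from the n and n+1 most stable genes
    (stability per :func:`genorm_rank`).  Reported as a diagnostic only;
    the consensus ranking does not use it.
    """
    result = genorm_rank(q)
    stability = list(reversed(result.exclusion_order))  # 3rd best .. worst
    ordered = [g for g in result.ranks.index if result.ranks[g] == 1] + stability
    top = len(ordered) if max_genes is None else min(max_genes, len(ordered))
    log2q = q.log2()
    rows = []
    for n in range(2, top):
        nf_n = log2q.loc[ordered[:n]].mean(axis=0)
        nf_n1 = log2q.loc[ordered[: n + 1]].mean(axis=0)
        v = float(np.std(nf_n - nf_n1, ddof=1))
        rows.append({"n": n, "v": v})
    return pd.DataFrame(rows)
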