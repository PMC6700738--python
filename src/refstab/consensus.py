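"""Consensus aggregation of the three per-method stability rankings.

Each method (geNorm, NormFinder, BestKeeper) produces an integer rank
per gene, lower = more stable.  The consensus averages the three ranks
per gene and orders genes by ascending average to give the
comprehensive ranking.  Ties in the average are broken by the smallest
single-method rank, then by input order (both logged).

The arithmetic mean is the default aggregator; a geometric-mean switch
is provided for completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from refstab.bestkeeper import bestkeeper_rank, bestkeeper_stats
from refstab.ct_io import CtMatrix
from refstab.genorm import DEFAULT_M_THRESHOLD, GeNormResult, genorm_rank
from refstab.normfinder import NormFinderResult, normfinder_stability
from refstab.preprocess import QMatrix, q_transform

logger = logging.getLogger(__name__)

METHODS = ("genorm", "normfinder", "bestkeeper")


def aggregate_ranks(
    genorm_ranks: pd.Series,
    normfinder_ranks: pd.Series,
    bestkeeper_ranks: pd.Series,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Combine three per-method rank vectors into a consensus table.

    All three inputs must cover the same gene set.  Returns a DataFrame
    ordered by ``comprehensive_rank`` with columns ``gene,
    genorm_rank, normfinder_rank, bestkeeper_rank, average,
    comprehensive_rank``.  The ``average`` column carries full
    precision; 3-decimal formatting is applied on write.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean type {mean!r}")
    genes = list(genorm_ranks.index)
    for name, ranks in (
        ("normfinder", normfinder_ranks),
        ("bestkeeper", bestkeeper_ranks),
    ):
        diff = set(genes).symmetric_difference(ranks.index)
        if diff:
            raise ValueError(
                f"gene sets differ between genorm and {name}: {sorted(diff)}"
            )
    table = pd.DataFrame(
        {
            "gene": genes,
            "genorm_rank": genorm_ranks[genes].astype(int).values,
            "normfinder_rank": normfinder_ranks[genes].astype(int).values,
            "bestkeeper_rank": bestkeeper_ranks[genes].astype(int).values,
        }
    )
    rank_cols = table[["genorm_rank", "normfinder_rank", "bestkeeper_rank"]]
    if mean == "arithmetic":
        table["average"] = rank_cols.mean(axis=1)
    else:
        table["average"] = gmean(rank_cols.to_numpy(), axis=1)
    best_single = rank_cols.min(axis=1)
    order = sorted(
        range(len(table)),
        key=lambda i: (table["average"].iat[i], best_single.iat[i], i),
    )
    comp = np.empty(len(table), dtype=int)
    for pos, i in enumerate(order, start=1):
        comp[i] = pos
    tied = table["average"].duplicated(keep=False)
    if tied.any():
        logger.info(
            "consensus: average ties broken by best single-method rank for %s",
            table.loc[tied, "gene"].tolist(),
        )
    table["comprehensive_rank"] = comp
    return table.sort_values("comprehensive_rank").reset_index(drop=True)


@dataclass
class EvaluationBundle:
    """Everything :func:`full_evaluation` produces in one pass."""

    qmatrix: QMatrix
    genorm: GeNormResult
    normfinder: NormFinderResult
    bestkeeper: pd.DataFrame  # stats with a "rank" column
    consensus: pd.DataFrame


def full_evaluation(
    ct: CtMatrix,
    m_threshold: float = DEFAULT_M_THRESHOLD,
    sd: str = "mad",
    mean: str = "arithmetic",
) -> EvaluationBundle:
    """Run the whole stability pipeline on a Ct matrix.

    Converts to Q, scores every complete gene with the three methods,
    and aggregates their rankings.  BestKeeper is restricted to the
    complete genes so the three rank vectors cover the same set.
    Deterministic given input and configuration.
    """
    q = q_transform(ct)
    try:
        gn = genorm_rank(q, threshold=m_threshold)
    except Exception as exc:
        raise RuntimeError(f"genorm stage failed: {exc}") from exc
    try:
        nf = normfinder_stability(q)
    except Exception as exc:
        raise RuntimeError(f"normfinder stage failed: {exc}") from exc
    try:
        bk = bestkeeper_stats(ct, sd=sd)
        bk = bk[bk["gene"].isin(q.gene_ids)].reset_index(drop=True)
        bk_ranks = bestkeeper_rank(bk)
        bk["rank"] = bk_ranks.values
    except Exception as exc:
        raise RuntimeError(f"bestkeeper stage failed: {exc}") from exc
    try:
        cons = aggregate_ranks(gn.ranks, nf.ranks, bk_ranks, mean=mean)
    except Exception as exc:
        raise RuntimeError(f"consensus stage failed: {exc}") from exc
    return EvaluationBundle(
        qmatrix=q, genorm=gn, normfinder=nf, bestkeeper=bk, consensus=cons
    )
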