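"""BestKeeper descriptive stability on raw Ct values.

BestKeeper characterises each candidate by the dispersion of its raw Ct
values: the "SD" of the original applet is the mean absolute deviation
from the arithmetic mean (in cycles), and CV = 100 * SD / mean (percent
of cycles).  Smaller SD and CV indicate a more stable candidate; an SD
above 1 cycle conventionally flags the gene as unstable.  Ranking is by
ascending CV with SD as tie-breaker.

The mean-absolute-deviation convention is the default; ``sd="classic"``
switches to the n-1 sample standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata

from refstab.ct_io import CtMatrix

logger = logging.getLogger(__name__)

#: SD (cycles) above which a candidate is flagged unstable.
SD_INSTABILITY_CUTOFF = 1.0


def bestkeeper_stats(ct: CtMatrix, sd: str = "mad") -> pd.DataFrame:
    """Per-gene BestKeeper descriptive statistics.

    Uses each gene's non-missing samples; genes with fewer than 2
    usable values are excluded with a log entry.  Returns a DataFrame
    with columns ``gene, n, geo_mean, mean, min, max, sd, cv,
    unstable_flag`` in input gene order.

    Parameters
    ----------
    sd
        ``"mad"`` (default): mean absolute deviation from the
        arithmetic mean, the original applet's convention.
        ``"classic"``: n-1 sample standard deviation.
    """
    if sd not in ("mad", "classic"):
        raise ValueError(f"unknown sd convention {sd!r}")
    rows = []
    for gene in ct.gene_ids:
        vec = ct.values.loc[gene].dropna().to_numpy(dtype=float)
        if vec.size < 2:
            logger.info("bestkeeper_stats: excluding gene %r (<2 usable Ct)", gene)
            continue
        if (vec <= 0).any():
            raise ValueError(f"bestkeeper_stats: non-positive Ct for gene {gene!r}")
        am = float(vec.mean())
        if sd == "mad":
            disp = float(np.abs(vec - am).mean())
        else:
            disp = float(vec.std(ddof=1))
        rows.append(
            {
                "gene": gene,
                "n": int(vec.size),
                "geo_mean": float(gmean(vec)),
                "mean": am,
                "min": float(vec.min()),
                "max": float(vec.max()),
                "sd": disp,
                "cv": 100.0 * disp / am,
                "unstable_flag": disp > SD_INSTABILITY_CUTOFF,
            }
        )
    if not rows:
        raise ValueError("no gene has >= 2 usable Ct values")
    return pd.DataFrame(rows)


def bestkeeper_rank(stats: pd.DataFrame) -> pd.Series:
    """Ranks by ascending CV, ties broken by ascending SD.

    Competition ranks: genes tied on both CV and SD share the smaller
    rank.  Returns a Series indexed by gene.
    """
    if len(stats) == 0:
        raise ValueError("bestkeeper_rank: empty stats table")
    key = list(zip(stats["cv"], stats["sd"]))
    order = sorted(range(len(key)), key=lambda i: key[i])
    ranks = np.empty(len(key), dtype=int)
    for pos, i in enumerate(order, start=1):
        # competition rank: share rank with an exactly equal predecessor
        prev = order[pos - 2] if pos > 1 else None
        if prev is not None and key[i] == key[prev]:
            ranks[i] = ranks[prev]
        else:
            ranks[i] = pos
    return pd.Series(ranks, index=stats["gene"].tolist())


def bestkeeper_index(ct: CtMatrix) -> pd.Series:
    """Optional diagnostic: per-sample geometric mean Ct across candidates.

    The classic BestKeeper index; excluded from ranking.
    """
    vals = ct.values.dropna(axis=0, how="any")
    return pd.Series(gmean(vals.to_numpy(), axis=0), index=ct.sample_ids)


def index_correlations(ct: CtMatrix) -> pd.DataFrame:
    """Optional diagnostic: Pearson r of each gene's Ct vs the index."""
    idx = bestkeeper_index(ct)
    rows = []
    for gene in ct.gene_ids:
        vec = ct.values.loc[gene]
        ok = vec.notna()
        if ok.sum() < 3:
            continue
        r = float(np.corrcoef(vec[ok], idx[ok])[0, 1])
        rows.append({"gene": gene, "pearson_r": r})
    return pd.DataFrame(rows)
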