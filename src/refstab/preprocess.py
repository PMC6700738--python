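"""Ct preprocessing: the Q transform and per-gene distribution summaries.

geNorm and NormFinder both operate on relative quantities rather than raw
cycle thresholds.  The conversion used throughout is

    Q(g, s) = 2 ** -(Ct(g, s) - min_s Ct(g, .))

so each gene's most abundant sample (lowest Ct) maps to Q = 1 and every
other sample to a value in (0, 1].  ``Ct_min`` is taken per gene within
the analysed matrix, which makes the transform invariant to adding a
constant to a gene's whole Ct vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refstab.ct_io import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class QMatrix:
    """Per-gene relative quantities in (0, 1], one row per complete gene.

    ``values`` is a genes x samples DataFrame; the per-gene maximum is
    exactly 1 by construction.  ``excluded`` lists genes dropped because
    they had missing Ct values (the transform needs complete vectors).
    """

    values: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> pd.DataFrame:
        """log2 Q, i.e. -(Ct - Ct_min) per gene."""
        return np.log2(self.values)


def q_transform(ct: CtMatrix) -> QMatrix:
    """Convert a Ct matrix to relative quantities.

    Genes with any missing Ct are excluded (with a log entry): the
    downstream stability models need complete per-sample vectors.  A
    gene must retain at least 2 usable values.
    """
    complete = ct.complete_genes()
    excluded = [g for g in ct.gene_ids if g not in complete]
    for g in excluded:
        logger.info("q_transform: excluding gene %r (missing Ct values)", g)
    sub = ct.values.loc[complete]
    if sub.shape[1] < 2:
        raise ValueError("q_transform needs at least 2 samples per gene")
    ct_min = sub.min(axis=1)
    q = np.exp2(-(sub.sub(ct_min, axis=0)))
    return QMatrix(q, excluded=excluded)


def ct_summary(ct: CtMatrix) -> pd.DataFrame:
    """Per-gene order statistics of the Ct distribution.

    Returns a DataFrame with columns ``gene, n, min, q1, median, q3,
    max, mean`` computed over each gene's non-missing samples.
    Quartiles use linear interpolation between order statistics.
    Genes with no usable value are excluded with a log entry.
    """
    rows = []
    for gene in ct.gene_ids:
        vec = ct.values.loc[gene].dropna().to_numpy()
        if vec.size == 0:
            logger.info("ct_summary: excluding gene %r (no usable Ct)", gene)
            continue
        rows.append(
            {
                "gene": gene,
                "n": int(vec.size),
                "min": float(vec.min()),
                "q1": float(np.quantile(vec, 0.25)),
                "median": float(np.median(vec)),
                "q3": float(np.quantile(vec, 0.75)),
                "max": float(vec.max()),
                "mean": float(vec.mean()),
            }
        )
    if not rows:
        raise ValueError("no gene has a usable Ct value")
    return pd.DataFrame(rows)
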