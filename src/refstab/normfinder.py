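"""NormFinder model-based stability for a single experimental group.

The model decomposes log2 relative quantities into a gene effect, a
sample (loading) effect, and gene-specific noise:

    y_ij = log2 Q_ij = alpha_i + beta_j + eps_ij,   eps_ij ~ (0, sigma_i^2)

With k genes and n samples, centering each sample over genes gives
d_ij = y_ij - mean_i y_ij, whose per-gene variance over samples,

    u_i = var_j(d_ij)                               (n-1 denominator)

is a biased estimate of sigma_i^2: the subtracted gene-average noise
leaks a share of every other gene's variance into u_i.  The bias-
corrected gene variance is

    sigma2_i = max(0, (k / (k - 2)) * (u_i - mean(u) / (k - 1)))

and the stability value is rho_i = sqrt(sigma2_i), in log2-cycle units;
lower means more stable.  The correction needs k >= 3 genes, and the
variance over samples needs n >= 3 for a usable estimate.

Only the single-group (ungrouped) form is implemented: a candidate
screen run on one condition has no between-group component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from refstab.preprocess import QMatrix


@dataclass
class NormFinderResult:
    """Per-gene NormFinder estimates and ranking.

    ``u`` is the raw per-gene variance of sample-centered log2
    quantities, ``sigma2`` the bias-corrected gene variance (floored at
    0) and ``rho = sqrt(sigma2)`` the stability value; ranks ascend by
    rho (competition ranks, lower = more stable).
    """

    u: pd.Series
    sigma2: pd.Series
    rho: pd.Series
    ranks: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.rho.index,
                "u": self.u.values,
                "sigma2": self.sigma2.values,
                "rho": self.rho.values,
                "rank": self.ranks.values,
            }
        )


def rank_by_score(scores, index=None) -> pd.Series:
    """Competition ranks for lower-is-better scores.

    Exact ties share the smaller rank and the next rank skips
    accordingly (1, 1, 3, ...).  Scores must be finite.
    """
    if isinstance(scores, pd.Series):
        index = scores.index if index is None else index
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("rank_by_score needs a non-empty 1-d score vector")
    if not np.isfinite(values).all():
        raise ValueError("rank_by_score: scores must be finite")
    ranks = rankdata(values, method="min").astype(int)
    if index is None:
        index = pd.RangeIndex(values.size)
    return pd.Series(ranks, index=index)


def normfinder_stability(q: QMatrix) -> NormFinderResult:
    """NormFinder stability values for every gene in a complete Q matrix."""
    y = q.log2()
    k, n = y.shape
    if k < 3:
        raise ValueError(f"normfinder_stability needs >= 3 genes, got {k}")
    if n < 3:
        raise ValueError(f"normfinder_stability needs >= 3 samples, got {n}")
    d = y - y.mean(axis=0)
    u = d.var(axis=1, ddof=1)
    u_bar = u.mean()
    sigma2 = (k / (k - 2)) * (u - u_bar / (k - 1))
    sigma2 = sigma2.clip(lower=0.0)
    rho = np.sqrt(sigma2)
    ranks = rank_by_score(rho)
    return NormFinderResult(u=u, sigma2=sigma2, rho=rho, ranks=ranks)
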