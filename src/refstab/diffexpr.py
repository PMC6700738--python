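"""Relative quantification against a reference gene and two-group tests.

Expression of target gene *g* in sample *s* relative to the chosen
normalizer *r* is

    rel(g, s) = 2 ** -(Ct_gs - Ct_rs)

i.e. the 2^-dCt estimator.  Because the reference Ct is subtracted per
sample, any global loading shift cancels exactly.  Two-group comparison
applies an unpaired Student's t-test (equal variances by default, Welch
by flag) to the per-sample relative levels, reports group means +/- SEM
rescaled so the control mean equals 1, the case/control fold change,
and flags significance at alpha (raw p, mirroring the usual qPCR
reporting).  Benjamini-Hochberg q-values are emitted as an extra column
but do not drive the flag.

By default the test runs on the linear-scale 2^-dCt values, matching
the mean +/- SEM bar-plot convention; ``on_dct=True`` tests the dCt
values instead (log scale).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from refstab.ct_io import CtMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def relative_expression(ct: CtMatrix, reference_gene: str) -> pd.DataFrame:
    """Per-sample 2^-dCt levels of every gene against a reference.

    The reference gene must be present with a Ct in every sample; it
    maps to 1.0 in each sample by construction.  Target cells with
    missing Ct propagate as NaN.
    """
    if reference_gene not in ct.gene_ids:
        raise ValueError(f"reference gene {reference_gene!r} not in the Ct table")
    ref = ct.values.loc[reference_gene]
    if ref.isna().any():
        bad = list(ref.index[ref.isna()])
        raise ValueError(
            f"reference gene {reference_gene!r} has missing Ct in samples {bad}"
        )
    dct = ct.values.sub(ref, axis=1)
    return np.exp2(-dct)


def _student_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate: no within-group variation
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def group_compare(
    levels: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    control_group: str | None = None,
    equal_var: bool = True,
    on_dct: bool = False,
) -> pd.DataFrame:
    """Two-group comparison of per-sample relative expression levels.

    Parameters
    ----------
    levels
        genes x samples frame of positive relative levels (2^-dCt).
    groups
        map sample -> group label; exactly two groups, each n >= 2.
    control_group
        the baseline group; defaults to a group named "control" (any
        case) if present, else the lexicographically first label.
    on_dct
        run the t-test on log2 levels (= -dCt) instead of the linear
        scale.

    Returns a DataFrame with columns ``gene, mean_control, sem_control,
    mean_case, sem_case, fold_change, t, p, q, significant,
    direction``.  Means and SEMs are rescaled so the control mean is
    exactly 1 per gene.
    """
    sample_groups = {s: groups[s] for s in levels.columns}
    labels = sorted(set(sample_groups.values()))
    if len(labels) != 2:
        raise ValueError(f"group_compare needs exactly 2 groups, got {labels}")
    if control_group is None:
        lowered = {lab.lower(): lab for lab in labels}
        control_group = lowered.get("control", labels[0])
    if control_group not in labels:
        raise ValueError(f"control group {control_group!r} not among {labels}")
    case_group = next(lab for lab in labels if lab != control_group)
    ctrl_samples = [s for s in levels.columns if sample_groups[s] == control_group]
    case_samples = [s for s in levels.columns if sample_groups[s] == case_group]
    if len(ctrl_samples) < 2 or len(case_samples) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for gene in levels.index:
        ctrl = levels.loc[gene, ctrl_samples].to_numpy(dtype=float)
        case = levels.loc[gene, case_samples].to_numpy(dtype=float)
        if np.isnan(ctrl).any() or np.isnan(case).any():
            logger.info("group_compare: skipping gene %r (missing levels)", gene)
            continue
        if (ctrl <= 0).any() or (case <= 0).any():
            raise ValueError(f"non-positive relative level for gene {gene!r}")
        if on_dct:
            t, p = _student_t(np.log2(case), np.log2(ctrl), equal_var)
        else:
            t, p = _student_t(case, ctrl, equal_var)
        scale = ctrl.mean()
        fc = case.mean() / ctrl.mean()
        rows.append(
            {
                "gene": gene,
                "mean_control": 1.0,
                "sem_control": float(stats.sem(ctrl) / scale),
                "mean_case": float(case.mean() / scale),
                "sem_case": float(stats.sem(case) / scale),
                "fold_change": float(fc),
                "t": t,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no gene with complete levels in both groups")
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    out["direction"] = np.where(
        ~out["significant"], "ns", np.where(out["fold_change"] > 1, "up", "down")
    )
    return out
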