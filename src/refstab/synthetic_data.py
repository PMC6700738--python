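"""Seeded generator of Ct matrices with planted stability structure.

The generator emulates the design of a small fecal-miRNA reference-gene
screen: 22 candidates (4 housekeeping genes + 18 miRNAs) measured in 5
control and 5 case samples, with per-gene baseline Ct values spanning
roughly 11-37 cycles.  The noise model is additive Gaussian on the Ct
(log2) scale — the standard qPCR error model:

    Ct(g, s) = mu_g + b_s + delta_g * [s in case group] + e_gs

with a shared per-sample loading effect b_s ~ N(0, tau^2), gene-specific
technical noise e_gs ~ N(0, sigma_g^2), and a per-gene case-group shift
delta_g (0 for non-differential genes).  Values are clipped (not
rejected) to the configured Ct window so a run is reproducible
seed-for-seed; clip events are logged.

:class:`SimTruth` records the planted parameters so recovery tests can
compare estimated stability orders against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from refstab.ct_io import CtMatrix, write_ct_matrix, write_sample_sheet
from refstab.datasets import published_stability_ranks

logger = logging.getLogger(__name__)

# Default panel: (gene, baseline Ct mu_g, noise sd sigma_g, case shift delta_g).
# Baselines follow the observed expression ordering of the emulated screen
# (5S rRNA most abundant at Ct ~12, mir-15a least at Ct ~35); noise SDs make
# mir-23a / GAPDH / let-7i the planted most-stable trio and mir-200b / 5s
# rRNA / mir-15a the least stable.  A +2-cycle shift (4-fold decrease) is
# planted in the 11 miRNAs reported down in the case condition.
_DEFAULT_PANEL = [
    ("mir-23a", 18.0, 0.10, 2.0),
    ("GAPDH", 18.5, 0.10, 0.0),
    ("let-7i", 14.0, 0.08, 0.0),
    ("mir-378", 19.0, 0.15, 2.0),
    ("mir-1224", 15.5, 0.15, 0.0),
    ("mir-155", 34.0, 0.18, 2.0),
    ("mir-574", 16.5, 0.18, 0.0),
    ("16S rRNA", 20.0, 0.22, 0.0),
    ("mir-29b", 24.0, 0.25, 2.0),
    ("let-7b", 25.0, 0.30, 0.0),
    ("mir-26b", 26.0, 0.35, 2.0),
    ("mir-141", 27.0, 0.40, 0.0),
    ("mir-200c", 28.0, 0.45, 0.0),
    ("mir-192", 16.0, 0.50, 2.0),
    ("let-7g", 23.0, 0.50, 0.0),
    ("mir-194", 17.0, 0.55, 2.0),
    ("let-7a", 22.0, 0.60, 2.0),
    ("mir-200a", 29.0, 0.70, 2.0),
    ("U6 snRNA", 15.0, 0.80, 0.0),
    ("mir-200b", 30.0, 1.20, 2.0),
    ("5s rRNA", 12.5, 1.00, 0.0),
    ("mir-15a", 35.0, 1.10, 2.0),
]


@dataclass
class SimConfig:
    """Planted parameters for one simulated Ct matrix.

    All Ct-scale quantities are in PCR cycles.  ``group_sizes`` and
    ``group_labels`` define the two conditions (control first); set the
    second size to 0 for a single-group screen.
    """

    gene_ids: list[str]
    baselines: np.ndarray  # mu_g, cycles
    noise_sd: np.ndarray  # sigma_g >= 0, cycles
    group_shift: np.ndarray  # delta_g, cycles, added in the case group
    sample_effect_sd: float = 0.5  # tau, cycles
    group_sizes: tuple[int, int] = (5, 5)
    group_labels: tuple[str, str] = ("control", "HCC")
    seed: int = 0
    ct_clip: tuple[float, float] = (0.5, 40.0)

    def __post_init__(self) -> None:
        self.baselines = np.asarray(self.baselines, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        self.group_shift = np.asarray(self.group_shift, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids in SimConfig")
        for name, arr in (
            ("baselines", self.baselines),
            ("noise_sd", self.noise_sd),
            ("group_shift", self.group_shift),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per gene")
        if (self.noise_sd < 0).any() or self.sample_effect_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.group_sizes[0] < 2 or (
            self.group_sizes[1] != 0 and self.group_sizes[1] < 2
        ):
            raise ValueError("group sizes must be >= 2 (or 0 for no case group)")
        lo, hi = self.ct_clip
        if not (0.0 < lo < hi < 45.0):
            raise ValueError("ct_clip window must lie within (0, 45)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    table: pd.DataFrame  # gene, sigma, delta, de_flag
    stability_order: list[str]  # genes by ascending planted sigma

    @classmethod
    def from_config(cls, config: SimConfig) -> "SimTruth":
        table = pd.DataFrame(
            {
                "gene": config.gene_ids,
                "sigma": config.noise_sd,
                "delta": config.group_shift,
                "de_flag": config.group_shift != 0,
            }
        )
        order = [
            config.gene_ids[i]
            for i in sorted(
                range(config.n_genes), key=lambda i: (config.noise_sd[i], i)
            )
        ]
        return cls(table=table, stability_order=order)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The canonical 22-gene x (5+5)-sample study-design configuration."""
    genes, mu, sigma, delta = zip(*_DEFAULT_PANEL)
    cfg = SimConfig(
        gene_ids=list(genes),
        baselines=np.array(mu),
        noise_sd=np.array(sigma),
        group_shift=np.array(delta),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_ct(config: SimConfig) -> tuple[CtMatrix, SimTruth]:
    """Draw one Ct matrix (and its ground truth) from a configuration.

    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_ctrl, n_case = config.group_sizes
    n_samples = n_ctrl + n_case
    ctrl_label, case_label = config.group_labels
    sample_ids = [f"{ctrl_label}_{i + 1}" for i in range(n_ctrl)] + [
        f"{case_label}_{i + 1}" for i in range(n_case)
    ]
    in_case = np.array([0] * n_ctrl + [1] * n_case)

    b = rng.normal(0.0, config.sample_effect_sd, size=n_samples)
    e = rng.normal(
        0.0, config.noise_sd[:, None], size=(config.n_genes, n_samples)
    )
    ct = (
        config.baselines[:, None]
        + b[None, :]
        + config.group_shift[:, None] * in_case[None, :]
        + e
    )
    lo, hi = config.ct_clip
    n_clipped = int(((ct < lo) | (ct > hi)).sum())
    if n_clipped:
        logger.info("simulate_ct: clipped %d cells to [%g, %g]", n_clipped, lo, hi)
    ct = np.clip(ct, lo, hi)

    groups = None
    if n_case > 0:
        groups = dict(zip(sample_ids, [ctrl_label] * n_ctrl + [case_label] * n_case))
    matrix = CtMatrix(
        pd.DataFrame(ct, index=config.gene_ids, columns=sample_ids), groups
    )
    return matrix, SimTruth.from_config(config)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical test fixtures to a directory.

    Emits the published 22-gene rank table (consensus worked example),
    a tiny hand-checkable 3-gene x 3-sample Ct matrix whose middle gene
    reproduces the textbook pairwise-variation example (log2 ratios
    0, -1, -2 against a flat partner, V = 1), and three seeded
    simulated Ct matrices with ground-truth sidecars.  Regenerating
    with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ranks_path = out / "published_ranks.csv"
    published_stability_ranks().to_csv(ranks_path, index=False)
    written["published_ranks"] = ranks_path

    hand = CtMatrix(
        pd.DataFrame(
            {
                "s1": [20.0, 20.0, 15.0],
                "s2": [20.0, 21.0, 15.5],
                "s3": [20.0, 22.0, 16.0],
            },
            index=["flat", "ramp", "half-ramp"],
        )
    )
    hand_path = out / "hand_3x3_ct.csv"
    write_ct_matrix(hand, hand_path)
    written["hand_3x3"] = hand_path

    for i in range(3):
        cfg = default_config(seed=seed + i)
        ct, truth = simulate_ct(cfg)
        ct_path = out / f"sim_{i}_ct.csv"
        write_ct_matrix(ct, ct_path)
        write_sample_sheet(ct.group_of, out / f"sim_{i}_samples.csv")
        truth.table.to_csv(out / f"sim_{i}_truth.csv", index=False)
        written[f"sim_{i}"] = ct_path
    return written
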