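"""Reading, validation and writing of Ct tables and sample metadata.

The on-disk dialect is a wide CSV/TSV: row 1 is a header whose first field
names the gene-id column ("gene") and whose remaining fields are sample
ids; each following row is one gene. Cells hold Ct values in PCR cycles;
the tokens ``""``, ``"NA"`` and ``"Undetermined"`` mark non-detects.
Delimiter is auto-detected between comma and tab. Decimal separator is
always the point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as a missing (non-detect) Ct cell.
MISSING_TOKENS = ("", "NA", "Undetermined")

#: Universal qPCR validity window for a Ct value, in cycles (exclusive).
CT_WINDOW = (0.0, 45.0)


class CtValidationError(ValueError):
    """Raised when a Ct table or sample sheet violates an input contract."""


@dataclass
class CtMatrix:
    """A gene x sample cycle-threshold matrix with optional group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; ``NaN``
        marks a non-detect.  Every non-missing Ct must be finite and lie
        strictly inside :data:`CT_WINDOW`.
    group_of
        Optional map ``sample id -> group label``.  When present it must
        cover every sample.
    """

    values: pd.DataFrame
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        validate_ct_frame(self.values)
        if self.group_of is not None:
            missing = [s for s in self.sample_ids if s not in self.group_of]
            if missing:
                raise CtValidationError(
                    f"group labels missing for samples: {missing}"
                )
            unknown = [s for s in self.group_of if s not in self.sample_ids]
            if unknown:
                raise CtValidationError(
                    f"metadata references unknown samples: {unknown}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the Ct is a non-detect."""
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def complete_genes(self) -> list[str]:
        """Gene ids with no missing value in any sample."""
        keep = ~self.values.isna().any(axis=1)
        return list(self.values.index[keep])

    def subset_samples(self, samples: list[str]) -> "CtMatrix":
        groups = None
        if self.group_of is not None:
            groups = {s: self.group_of[s] for s in samples}
        return CtMatrix(self.values[samples].copy(), groups)


def validate_ct_frame(values: pd.DataFrame) -> None:
    """Check a candidate Ct frame against the CtMatrix invariants."""
    dup_genes = values.index[values.index.duplicated()].unique().tolist()
    if dup_genes:
        raise CtValidationError(f"duplicate gene ids: {dup_genes}")
    dup_samples = values.columns[values.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise CtValidationError(f"duplicate sample ids: {dup_samples}")
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise CtValidationError(
            f"need at least 3 genes and 2 samples, got {values.shape}"
        )
    arr = values.to_numpy(dtype=float)
    finite = np.isfinite(arr)
    bad_inf = ~finite & ~np.isnan(arr)
    lo, hi = CT_WINDOW
    bad_range = finite & ((arr <= lo) | (arr >= hi))
    bad = bad_inf | bad_range
    if bad.any():
        cells = [
            f"({values.index[i]}, {values.columns[j]})={arr[i, j]}"
            for i, j in zip(*np.nonzero(bad))
        ]
        raise CtValidationError(
            f"Ct values outside the ({lo}, {hi}) cycle window: {cells}"
        )


def read_ct_table(path: str | Path, metadata_path: str | Path | None = None) -> CtMatrix:
    """Read a wide Ct CSV/TSV, optionally joined with a sample sheet.

    The first column holds gene ids; remaining columns are numeric Ct
    values or one of the declared missing tokens.  Column order is
    preserved.  Raises :class:`CtValidationError` on duplicate labels,
    out-of-window Ct values, non-numeric cells, or metadata that
    references unknown samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise CtValidationError(f"non-numeric Ct cell in {path.name}: {exc}") from exc
    groups = None
    if metadata_path is not None:
        groups = read_sample_sheet(metadata_path)
    return CtMatrix(df, groups)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a sample sheet CSV with columns ``sample_id,group``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sheet = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(sheet.columns):
        raise CtValidationError(
            f"sample sheet must have columns {sorted(required)}, got {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise CtValidationError(f"duplicate sample ids in sample sheet: {dup}")
    if sheet["group"].isna().any() or (sheet["group"].str.strip() == "").any():
        raise CtValidationError("empty group label in sample sheet")
    return dict(zip(sheet["sample_id"], sheet["group"]))


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with fixed formatting.

    Float columns are written with 3 decimals; integer-valued rank
    columns stay integers.  The written file round-trips through
    :func:`pandas.read_csv` up to that declared formatting.
    """
    if result is None or len(result) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, index=False, float_format="%.3f")
    logger.info("wrote %d rows to %s", len(result), path)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    """Write a CtMatrix back to the wide dialect read by :func:`read_ct_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = ct.values.copy()
    out.index.name = "gene"
    out.to_csv(path, float_format="%.4f")


def write_sample_sheet(group_of: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"sample_id": list(group_of), "group": list(group_of.values())}
    ).to_csv(path, index=False)
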