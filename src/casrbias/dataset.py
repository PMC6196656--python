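"""Replicate-level concentration-response data container and CSV I/O.

The canonical in-memory representation is a pandas DataFrame with one row per
measured well: columns ``genotype``, ``pathway``, ``conc_mM``, ``replicate``,
``response``. A scale tag records which normalisation the responses are on
(raw instrument units, percent of the wild-type maximum, or fold change over
the basal agonist concentration).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: canonical column order of the CSV dialect
CRC_COLUMNS = ["genotype", "pathway", "conc_mM", "replicate", "response", "scale"]

KNOWN_PATHWAYS = {"Ca", "pERK", "NFAT", "SRE"}


class Scale(str, enum.Enum):
    """Response scale of a dataset."""

    RAW = "raw"
    PERCENT_OF_WT_MAX = "percent_of_WT_max"
    FOLD_CHANGE_OVER_BASAL = "fold_change_over_basal"


class DatasetValidationError(ValueError):
    """Raised when a concentration-response table violates its invariants."""


@dataclass
class ConcentrationResponseDataset:
    """Replicate responses per genotype x pathway x agonist concentration.

    Parameters
    ----------
    data:
        DataFrame with columns ``genotype``, ``pathway``, ``conc_mM``,
        ``replicate``, ``response``.
    scale:
        Normalisation tag for the ``response`` column.
    """

    data: pd.DataFrame
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in CRC_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing column(s): {', '.join(missing)}")
        df["conc_mM"] = pd.to_numeric(df["conc_mM"], errors="raise")
        df["response"] = pd.to_numeric(df["response"], errors="raise")
        df["replicate"] = df["replicate"].astype(int)
        if len(df) == 0:
            raise DatasetValidationError("empty dataset")
        if (df["conc_mM"] <= 0).any():
            bad = df.index[df["conc_mM"] <= 0][0]
            raise DatasetValidationError(
                f"non-positive concentration at row {bad}: {df.loc[bad, 'conc_mM']} mM"
            )
        if not np.isfinite(df["response"]).all():
            bad = df.index[~np.isfinite(df["response"])][0]
            raise DatasetValidationError(f"non-finite response at row {bad}")
        dup = df.duplicated(subset=["genotype", "pathway", "conc_mM", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DatasetValidationError(
                "duplicate replicate key: "
                f"({row['genotype']}, {row['pathway']}, {row['conc_mM']}, {row['replicate']})"
            )
        self.data = df[CRC_COLUMNS[:-1]].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def pathways(self) -> list[str]:
        return sorted(self.data["pathway"].unique())

    def concentrations(self, genotype: str | None = None, pathway: str | None = None) -> np.ndarray:
        df = self.select(genotype, pathway).data
        return np.sort(df["conc_mM"].unique())

    def select(self, genotype: str | None = None, pathway: str | None = None) -> "ConcentrationResponseDataset":
        """Subset by genotype and/or pathway, preserving the scale tag."""
        df = self.data
        if genotype is not None:
            if genotype not in set(df["genotype"]):
                raise KeyError(f"genotype {genotype!r} not in dataset")
            df = df[df["genotype"] == genotype]
        if pathway is not None:
            if pathway not in set(df["pathway"]):
                raise KeyError(f"pathway {pathway!r} not in dataset")
            df = df[df["pathway"] == pathway]
        return ConcentrationResponseDataset(df.reset_index(drop=True), scale=self.scale)

    def cell_means(self) -> pd.DataFrame:
        """Per (genotype, pathway, concentration) mean response."""
        return (
            self.data.groupby(["genotype", "pathway", "conc_mM"], as_index=False)["response"]
            .mean()
            .sort_values(["genotype", "pathway", "conc_mM"])
            .reset_index(drop=True)
        )

    def with_responses(self, responses: Iterable[float], scale: Scale) -> "ConcentrationResponseDataset":
        df = self.data.copy()
        df["response"] = np.asarray(list(responses), dtype=float)
        return ConcentrationResponseDataset(df, scale=scale)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        """Write the dataset in the pipeline CSV dialect (one row per well)."""
        path = Path(path)
        out = self.data.copy()
        out["scale"] = self.scale.value
        # shortest round-trip repr so doubles survive the text round-trip exactly
        for col in ("conc_mM", "response"):
            out[col] = out[col].map(lambda v: repr(float(v)))
        out.to_csv(path, index=False, columns=CRC_COLUMNS)
        return path

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationResponseDataset):
            return NotImplemented
        return self.scale == other.scale and self.data.equals(other.data)


def read_crc_csv(path: str | Path) -> ConcentrationResponseDataset:
    """Read a concentration-response CSV with header
    ``genotype,pathway,conc_mM,replicate,response,scale``.

    Raises
    ------
    DatasetValidationError
        On a missing column, a non-positive concentration, a non-numeric
        response (the offending row is named), duplicate replicate keys, or
        inconsistent scale tags.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CRC_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in ("conc_mM", "response"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise DatasetValidationError(
                f"{path}: non-numeric {col} at row {bad[0] + 2} (value {df.loc[bad[0], col]!r})"
            )
        df[col] = coerced
    scales = df["scale"].unique()
    if len(scales) != 1:
        raise DatasetValidationError(f"{path}: mixed scale tags {sorted(scales)}")
    try:
        scale = Scale(scales[0])
    except ValueError as exc:
        raise DatasetValidationError(f"{path}: unknown scale tag {scales[0]!r}") from exc
    neg = df.index[df["conc_mM"] <= 0]
    if len(neg):
        raise DatasetValidationError(
            f"{path}: non-positive conc_mM at row {neg[0] + 2} (value {df.loc[neg[0], 'conc_mM']})"
        )
    return ConcentrationResponseDataset(df.drop(columns=["scale"]), scale=scale)
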