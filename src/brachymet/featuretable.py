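"""Aligned LC-MS feature tables with the factorial organ x line design.

A feature table is an m/z-feature x sample intensity matrix plus two
metadata frames: per-feature (m/z, retention time, ionization polarity)
and per-sample (organ, line, experiment block, replicate).  Positive-
and negative-mode features live in one table, distinguished by the
polarity column, and are analysed jointly.

Preprocessing mirrors common practice for detection-limited data:
below-LOD entries (missing or zero) are substituted with half of the
per-feature minimum non-zero observation, then intensities are log2
transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ORGANS = ("leaf", "root", "spike")
LINES = ("Bd21", "Bd3-1")
POLARITIES = ("positive", "negative")

DESIGN_COLUMNS = ["sample_id", "organ", "line", "experiment", "replicate"]
FEATURE_COLUMNS = ["feature_id", "mz", "rt", "polarity"]


class FormatError(ValueError):
    """Malformed feature-table or design file."""


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    organ: str
    line: str
    experiment: str
    replicate: int

    def __post_init__(self):
        if self.organ not in ORGANS:
            raise FormatError(f"unknown organ {self.organ!r} for sample {self.sample_id}")
        if self.line not in LINES:
            raise FormatError(f"unknown line {self.line!r} for sample {self.sample_id}")
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1 for sample {self.sample_id}")


@dataclass(frozen=True)
class Feature:
    feature_id: str
    mz: float
    rt: float
    polarity: str

    def __post_init__(self):
        if self.mz <= 0:
            raise FormatError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise FormatError(f"feature {self.feature_id}: rt must be >= 0")
        if self.polarity not in POLARITIES:
            raise FormatError(f"feature {self.feature_id}: unknown polarity {self.polarity!r}")


class FeatureTable:
    """Feature x sample intensity matrix with design metadata.

    ``intensities`` is a float DataFrame indexed by feature_id with
    sample_id columns; missing (below-LOD) entries are NaN.
    """

    def __init__(self, features: pd.DataFrame, design: pd.DataFrame,
                 intensities: pd.DataFrame, transformed: str = "raw"):
        features = features.reset_index(drop=True)
        design = design.reset_index(drop=True)
        if transformed not in ("raw", "log2"):
            raise ValueError("transformed must be 'raw' or 'log2'")
        if list(intensities.index) != list(features["feature_id"]):
            raise FormatError("intensity rows do not match feature list")
        if list(intensities.columns) != list(design["sample_id"]):
            raise FormatError("intensity columns do not match design sample ids")
        if design["sample_id"].duplicated().any():
            dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if features["feature_id"].duplicated().any():
            dup = features.loc[features["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise FormatError(f"duplicate feature id {dup!r}")
        key = design[["organ", "line", "experiment", "replicate"]]
        if key.duplicated().any():
            raise FormatError("(organ, line, experiment, replicate) must uniquely identify samples")
        # validate labels via the dataclasses
        for row in design.itertuples(index=False):
            SampleDesign(str(row.sample_id), row.organ, row.line,
                         str(row.experiment), int(row.replicate))
        for row in features.itertuples(index=False):
            Feature(str(row.feature_id), float(row.mz), float(row.rt), row.polarity)
        self.features = features
        self.design = design
        self.intensities = intensities.astype(float)
        self.transformed = transformed

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.design.copy(),
                            self.intensities.copy(), self.transformed)

    def samples_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        for col, val in criteria.items():
            mask &= self.design[col] == val
        return list(self.design.loc[mask, "sample_id"])


def canonical_design(n_replicates: int = 4,
                     experiments: Iterable[str] = ("E1", "E2")) -> pd.DataFrame:
    """The full factorial design: 3 organs x 2 lines x 2 blocks x n reps."""
    rows = []
    for organ in ORGANS:
        for line in LINES:
            for exp in experiments:
                for rep in range(1, n_replicates + 1):
                    sid = f"{organ}_{line}_{exp}_r{rep}"
                    rows.append((sid, organ, line, exp, rep))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def read_feature_table(path: str | Path, design_path: str | Path) -> FeatureTable:
    """Read a TSV feature table plus its sidecar design TSV."""
    path, design_path = Path(path), Path(design_path)
    raw = pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                      float_precision="round_trip")
    for col in FEATURE_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str, "experiment": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"{design_path}: missing design columns {missing}")
    sample_cols = [c for c in raw.columns if c not in FEATURE_COLUMNS]
    if sorted(sample_cols) != sorted(design["sample_id"].astype(str)):
        extra = sorted(set(sample_cols) - set(design["sample_id"]))
        lacking = sorted(set(design["sample_id"]) - set(sample_cols))
        raise FormatError(
            f"{path}: sample columns do not match design "
            f"(unmatched columns {extra}, missing columns {lacking})")
    features = raw[FEATURE_COLUMNS].copy()
    intensities = raw[list(design["sample_id"])].copy()
    intensities.index = features["feature_id"]
    return FeatureTable(features, design, intensities)


def write_feature_table(table: FeatureTable, path: str | Path,
                        design_path: str | Path) -> None:
    """Write the TSV dialect that ``read_feature_table`` consumes."""
    out = pd.concat(
        [table.features.reset_index(drop=True),
         table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="")
    table.design.to_csv(design_path, sep="\t", index=False)


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Substitute below-LOD entries with half the per-feature minimum.

    Missing entries and exact zeros are both treated as below the
    detection limit.  Features with no observed value at all are dropped
    (with a logged warning), not imputed.
    """
    if table.transformed != "raw":
        raise ValueError("impute_half_min expects a raw-intensity table")
    mat = table.intensities.to_numpy(copy=True)
    mat[mat == 0] = np.nan
    all_missing = np.isnan(mat).all(axis=1)
    if all_missing.any():
        dropped = list(table.features.loc[all_missing, "feature_id"])
        log.warning("dropping %d feature(s) with no observed values: %s",
                    len(dropped), ", ".join(dropped[:10]))
    keep = ~all_missing
    mat = mat[keep]
    row_min = np.nanmin(mat, axis=1)
    fill = np.where(np.isnan(mat), 0.5 * row_min[:, None], mat)
    features = table.features.loc[keep].reset_index(drop=True)
    intensities = pd.DataFrame(fill, index=features["feature_id"],
                               columns=table.intensities.columns)
    return FeatureTable(features, table.design, intensities, "raw")


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise log2 of an imputed table (all entries must be > 0)."""
    mat = table.intensities.to_numpy()
    bad = ~(mat > 0)
    if bad.any():
        fid = table.features.loc[bad.any(axis=1), "feature_id"].iloc[0]
        raise ValueError(f"non-positive intensity for feature {fid!r}; impute first")
    intensities = pd.DataFrame(np.log2(mat), index=table.intensities.index,
                               columns=table.intensities.columns)
    return FeatureTable(table.features, table.design, intensities, "log2")


def preprocess(table: FeatureTable) -> FeatureTable:
    """Half-minimum imputation followed by log2 transform."""
    return log2_transform(impute_half_min(table))


def write_mztab_sml(table: FeatureTable, path: str | Path) -> None:
    """Minimal mzTab-M-style small-molecule (SML) section for the feature list."""
    with open(path, "w") as fh:
        fh.write("SMH\tSML_ID\texp_mass_to_charge\tretention_time_in_minutes\tadduct_ions\n")
        for row in table.features.itertuples(index=False):
            adduct = "[M+H]1+" if row.polarity == "positive" else "[M-H]1-"
            fh.write(f"SML\t{row.feature_id}\t{row.mz:.5f}\t{row.rt:.3f}\t{adduct}\n")
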