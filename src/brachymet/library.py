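"""Bundled reference resources: the 93-compound identification library
and the miniature compound/pathway database.

The compound library is a transcription of the published identification
table for Brachypodium leaves, roots and spikes: name, chemical formula,
ion type, measured and calculated m/z, ppm error, MS^n fragmentation
pathways (with base-peak markers), detection organs, and MSI
identification level.  Rows whose printed numbers are internally
inconsistent (measured mass, calculated mass and ppm error cannot all be
true simultaneously, beyond the rounding of the printed measured mass)
carry consistency_flag='printed-inconsistency'; they are transcribed as
printed, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .chemmass import ElementalFormula, IonSpecies, ion_mz, parse_formula

__all__ = ["CompoundRecord", "load_compound_library", "library_dataframe",
           "COMPOUND_CLASSES"]

COMPOUND_CLASSES = (
    "hydroxycinnamate-quinate", "hydroxycinnamate-threonate", "amide",
    "flavone-O-glycoside", "flavone-C-glycoside", "flavone-O,C-glycoside",
    "di-C-glycoside", "proanthocyanidin", "lignan", "amino-acid", "other",
)


@dataclass(frozen=True)
class CompoundRecord:
    """One reference-library row."""

    compound_id: str
    name: str
    formula: Optional[ElementalFormula]
    ion_type: IonSpecies
    measured_mz: float
    printed_calc_mz: Optional[float]
    printed_delta_ppm: Optional[float]
    msn_negative: str
    msn_positive: str
    organs: frozenset
    msi_level: int
    std: bool
    compound_class: str
    consistency_flag: str
    chebi: str = ""
    rt_minutes: Optional[float] = None
    measured_decimals: int = field(default=5)

    @property
    def polarity(self) -> str:
        return self.ion_type.polarity

    @property
    def theoretical_mz(self) -> Optional[float]:
        """Formula-derived ion m/z, None when no formula is printed."""
        if self.formula is None:
            return None
        return ion_mz(self.formula, self.ion_type)


def _library_path():
    return resources.files("brachymet.data").joinpath("compound_library.tsv")


def library_dataframe() -> pd.DataFrame:
    """The raw bundled library as a DataFrame (printed values as strings)."""
    with resources.as_file(_library_path()) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def load_compound_library() -> list[CompoundRecord]:
    records = []
    for row in library_dataframe().itertuples(index=False):
        formula = None
        if row.formula:
            try:
                formula = parse_formula(row.formula)
            except ValueError:
                formula = None
        records.append(CompoundRecord(
            compound_id=row.compound_id,
            name=row.name,
            formula=formula,
            ion_type=IonSpecies(row.ion_type),
            measured_mz=float(row.measured_mz),
            printed_calc_mz=float(row.printed_calc_mz) if row.printed_calc_mz else None,
            printed_delta_ppm=float(row.printed_delta_ppm) if row.printed_delta_ppm else None,
            msn_negative=row.msn_negative,
            msn_positive=row.msn_positive,
            organs=frozenset(row.organs.split(",")) if row.organs else frozenset(),
            msi_level=int(row.msi_level),
            std=row.std == "yes",
            compound_class=row.compound_class,
            consistency_flag=row.consistency_flag,
            chebi=row.chebi,
            measured_decimals=len(row.measured_mz.split(".")[1]),
        ))
    return records
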