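"""Spectral-count proteomics summary of tape-strip protein isolates.

Spectral counting is a crude label-free abundance proxy: the number of MS/MS
spectra matched to peptides of a protein, here normalized by molecular
weight to correct for the number of observable peptides a larger protein
offers.  The abundance index is

    index = total peptide count / molecular weight (Da) x 10^3,

conventionally reported to two decimals.  The keratin-derived fraction of
all spectral counts quantifies how keratin-dominated a tape-strip isolate
is: uninvolved stratum corneum is ~98% keratin by this measure, while
psoriatic plaques carry a substantial admixture of inflammatory,
antimicrobial and epithelial-organization proteins.

Bundled with the package are single-subject pilot spectral-count tables
from tape-strip isolates of uninvolved and psoriatic skin (the psoriatic
table lists only the most prominent proteins of the ~66 detected, so its
keratin fraction describes that subset, not the full isolate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "SpectralCountRecord",
    "SpectralCountTable",
    "abundance_index",
    "rank_by_abundance",
    "keratin_fraction",
    "is_keratin",
    "load_reference_table",
    "summarize_table",
]

SPECTRAL_COLUMNS = ["protein_name", "unique_peptides", "total_peptide_count", "mol_wt_da"]


@dataclass(frozen=True)
class SpectralCountRecord:
    """One protein's spectral-count entry."""

    protein_name: str
    unique_peptides: int
    total_peptide_count: int
    mol_wt: float

    def __post_init__(self) -> None:
        if not self.protein_name:
            raise InvalidInputError("protein_name must be non-empty")
        if self.unique_peptides < 1:
            raise InvalidInputError("unique_peptides must be >= 1")
        if self.total_peptide_count < self.unique_peptides:
            raise InvalidInputError("total_peptide_count must be >= unique_peptides")
        if self.mol_wt <= 0:
            raise InvalidInputError("mol_wt must be positive")


@dataclass(frozen=True)
class SpectralCountTable:
    """Spectral-count records for one condition (uninvolved or psoriatic)."""

    condition: str
    records: tuple[SpectralCountRecord, ...]

    def __post_init__(self) -> None:
        names = [r.protein_name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidInputError(f"duplicate protein names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str) -> "SpectralCountTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SPECTRAL_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"{path}: missing columns {missing}")
        records = []
        for i, row in df.iterrows():
            try:
                records.append(
                    SpectralCountRecord(
                        protein_name=str(row["protein_name"]),
                        unique_peptides=int(row["unique_peptides"]),
                        total_peptide_count=int(row["total_peptide_count"]),
                        mol_wt=float(row["mol_wt_da"]),
                    )
                )
            except (InvalidInputError, ValueError) as exc:
                # +2: one for the header, one for 1-based numbering
                raise InvalidInputError(f"{path}, line {i + 2}: {exc}") from exc
        return cls(condition=condition, records=tuple(records))

    def to_dataframe(self, with_index: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein_name": [r.protein_name for r in self.records],
                "unique_peptides": [r.unique_peptides for r in self.records],
                "total_peptide_count": [r.total_peptide_count for r in self.records],
                "mol_wt_da": [r.mol_wt for r in self.records],
            }
        )
        if with_index:
            df["abundance_index"] = [round(abundance_index(r), 2) for r in self.records]
        return df


def abundance_index(record: SpectralCountRecord) -> float:
    """Total peptide count over molecular weight, times 10^3 (unrounded).

    Round to 2 decimals for reporting, per the conventional
    "peptide count / mol wt x 10^3" column.
    """
    if record.mol_wt <= 0:
        raise InvalidInputError("mol_wt must be positive")
    return record.total_peptide_count / record.mol_wt * 1e3


def rank_by_abundance(table: SpectralCountTable) -> SpectralCountTable:
    """Records sorted by descending abundance index.

    Ties break by descending total peptide count, then protein name.
    """
    if not table.records:
        raise InsufficientDataError("cannot rank an empty table")
    ordered = sorted(
        table.records,
        key=lambda r: (-abundance_index(r), -r.total_peptide_count, r.protein_name),
    )
    return replace(table, records=tuple(ordered))


def is_keratin(name: str, extra_keratins: Iterable[str] = ()) -> bool:
    """Name-based keratin classifier: a "Keratin" prefix (case-insensitive),
    plus any explicit override names."""
    return name.lower().startswith("keratin") or name in set(extra_keratins)


def keratin_fraction(
    table: SpectralCountTable,
    classifier: Callable[[str], bool] | None = None,
) -> float:
    """Percent of total spectral counts from keratin-classified proteins."""
    if not table.records:
        raise InsufficientDataError("cannot compute a fraction on an empty table")
    if classifier is None:
        classifier = is_keratin
    total = sum(r.total_peptide_count for r in table.records)
    if total <= 0:
        raise InvalidInputError("table has zero total spectral counts")
    keratin = sum(
        r.total_peptide_count for r in table.records if classifier(r.protein_name)
    )
    return 100.0 * keratin / total


def load_reference_table(condition: str) -> SpectralCountTable:
    """Load the bundled pilot spectral-count table for one condition
    ("uninvolved" or "psoriatic")."""
    if condition not in ("uninvolved", "psoriatic"):
        raise InvalidInputError("condition must be 'uninvolved' or 'psoriatic'")
    ref = resources.files("epiturn.data") / f"spectral_counts_{condition}.tsv"
    with resources.as_file(ref) as path:
        return SpectralCountTable.from_tsv(path, condition=condition)


def summarize_table(table: SpectralCountTable) -> dict:
    """JSON-ready summary: condition, keratin percent (whole-percent
    convention), protein count, and the top-ranked protein.

    A psoriatic table typically lists only the most prominent proteins, in
    which case the keratin percent describes that subset, flagged by
    ``subset_only``.
    """
    ranked = rank_by_abundance(table)
    return {
        "condition": table.condition,
        "n_proteins": len(table),
        "keratin_percent": round(keratin_fraction(table)),
        "keratin_percent_raw": keratin_fraction(table),
        "top_protein": ranked.records[0].protein_name,
        "subset_only": table.condition == "psoriatic",
    }
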