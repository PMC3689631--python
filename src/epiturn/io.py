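"""Delimited-text readers/writers, run configuration and output manifests.

All study tables are plain CSV/TSV:

- saliva:       subject_id, day, enrichment_fraction
- dosing:       subject_id, day, volume_ml, purity
- tape strips:  subject_id, site_id, lesional (0/1), day, em1
- TEWL:         subject_id, site_id, lesional (0/1), day, reading_1[, reading_2]
- spectral:     protein_name, unique_peptides, total_peptide_count, mol_wt_da (TSV)

Every command writes a manifest recording the seed and a hash of the
effective configuration, so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .kinetics import FitConfig
from .proteomics import SpectralCountTable
from .synthetic import CohortBundle
from .tewl import TEWLRecord

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_saliva",
    "read_tape_strips",
    "read_tewl",
    "write_cohort",
    "read_cohort",
    "write_manifest",
]

SALIVA_COLUMNS = ["subject_id", "day", "enrichment_fraction"]
DOSING_COLUMNS = ["subject_id", "day", "volume_ml", "purity"]
TAPE_COLUMNS = ["subject_id", "site_id", "lesional", "day", "em1"]
TEWL_COLUMNS = ["subject_id", "site_id", "lesional", "day", "reading_1"]

SALIVA_FILE = "saliva.csv"
DOSING_FILE = "dosing.csv"
TAPE_FILE = "tape_strips.csv"
TEWL_FILE = "tewl.csv"
TRUTH_FILE = "truth.json"


@dataclass(frozen=True)
class RunConfig:
    """Analysis run configuration with CLI-overridable defaults."""

    input_dir: str = "."
    output_dir: str = "results"
    seed: int = 0
    analyte_formula: dict = field(
        default_factory=lambda: {"C": 10, "H": 8, "F": 5, "N": 1, "O": 2}
    )
    amplification: float = 2.7
    n_label_sites: int = 4
    fit: FitConfig = field(default_factory=FitConfig)
    appearance_threshold: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a JSON run configuration, naming any missing/unknown key."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: config must be a JSON object")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {unknown}")
    fit_raw = raw.pop("fit", {})
    unknown_fit = sorted(set(fit_raw) - set(FitConfig.__dataclass_fields__))
    if unknown_fit:
        raise InvalidInputError(f"{path}: unknown fit config keys {unknown_fit}")
    return RunConfig(**raw, fit=FitConfig(**fit_raw))


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


def read_saliva(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SALIVA_COLUMNS, path)
    return df


def read_tape_strips(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TAPE_COLUMNS, path)
    return df


def read_tewl(path: str | Path) -> list[TEWLRecord]:
    df = pd.read_csv(path)
    _require_columns(df, TEWL_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        readings = [row["reading_1"]]
        if "reading_2" in df.columns and pd.notna(row.get("reading_2")):
            readings.append(row["reading_2"])
        try:
            records.append(
                TEWLRecord(
                    subject_id=str(row["subject_id"]),
                    site_id=str(row["site_id"]),
                    lesional=bool(int(row["lesional"])),
                    day=float(row["day"]),
                    readings=tuple(float(r) for r in readings),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write a synthetic cohort to disk in the dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.dosing.to_csv(out / DOSING_FILE, index=False)
    bundle.saliva.to_csv(out / SALIVA_FILE, index=False)
    bundle.tape_strips.to_csv(out / TAPE_FILE, index=False)
    bundle.tewl.to_csv(out / TEWL_FILE, index=False)
    for condition, table in bundle.spectral.items():
        table.to_dataframe(with_index=False).to_csv(
            out / f"spectral_counts_{condition}.tsv", sep="\t", index=False
        )
    with open(out / TRUTH_FILE, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return out


def read_cohort(in_dir: str | Path) -> CohortBundle:
    """Read a cohort directory back into a bundle (round-trip of write_cohort)."""
    in_dir = Path(in_dir)
    for name in (SALIVA_FILE, TAPE_FILE):
        if not (in_dir / name).exists():
            raise InvalidInputError(f"missing input file: {in_dir / name}")
    dosing_path = in_dir / DOSING_FILE
    dosing = pd.read_csv(dosing_path) if dosing_path.exists() else pd.DataFrame(
        columns=DOSING_COLUMNS
    )
    tewl_path = in_dir / TEWL_FILE
    tewl = pd.read_csv(tewl_path) if tewl_path.exists() else pd.DataFrame(
        columns=TEWL_COLUMNS
    )
    spectral = {}
    for condition in ("uninvolved", "psoriatic"):
        p = in_dir / f"spectral_counts_{condition}.tsv"
        if p.exists():
            spectral[condition] = SpectralCountTable.from_tsv(p, condition=condition)
    truth_path = in_dir / TRUTH_FILE
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return CohortBundle(
        dosing=dosing,
        saliva=read_saliva(in_dir / SALIVA_FILE),
        tape_strips=read_tape_strips(in_dir / TAPE_FILE),
        tewl=tewl,
        spectral=spectral,
        truth=truth,
    )


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Write a manifest with the seed and a SHA-256 hash of the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(json.dumps(config, default=str)),
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
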