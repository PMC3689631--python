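"""Seeded synthetic cohorts with the statistical structure of a heavy-water
tape-strip labeling study.

The generator forward-simulates the whole measurement chain for a small
psoriasis cohort: a twice-daily Monday-Friday 50 mL x 70% 2H2O protocol over
16-38 days, one-compartment body-water enrichment sampled as saliva on
tape-strip days, per-site conveyor kinetics mapped through the MIDA plateau
to alanine EM1 with multiplicative GC/MS noise, duplicate TEWL readings with
lesional means well above non-lesional, and spectral-count tables drawn
multinomially from the bundled pilot proportions.

Kinetic truth is anchored on *detection*: the first sampling day at which a
site's label crosses the appearance threshold is drawn uniformly from the
study's observed windows (lesional 3-8 days, uninvolved 10-20 days), and the
transit lag tau is placed between the preceding sampling day and that day,
on the quarter-day lattice the fitter resolves.  Uninvolved lags always
exceed the same subject's lesional lags.  Every site's true (tau, k) is
recorded for closed-loop recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .body_water import (
    BodyWaterParams,
    DosingSchedule,
    build_protocol_schedule,
    interpolate_measured,
    simulate_body_water,
    time_averaged_enrichment,
)
from .errors import InvalidInputError
from .isotopomers import (
    DEFAULT_ANALYTE,
    ElementalFormula,
    LabelingModel,
    default_labeling_model,
    em1_max,
)
from .kinetics import DEFAULT_APPEARANCE_THRESHOLD, predict_f
from .proteomics import SpectralCountRecord, SpectralCountTable, load_reference_table

__all__ = ["CohortConfig", "CohortBundle", "generate_cohort", "truth_report"]

#: Tape-strip sampling-day menu: a 2-5 day cadence that includes both
#: detection-window edges (day 8 lesional, day 20 uninvolved); each subject
#: uses the prefix within their dosing duration.
SAMPLING_DAY_MENU = (3, 6, 8, 10, 13, 15, 17, 20, 24, 28, 31, 35, 38)

#: Lag lattice matching the fitter's tau grid resolution (days).
TAU_LATTICE = 0.25

LESIONAL_WINDOW = (3.0, 8.0)
UNINVOLVED_WINDOW = (10.0, 20.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for cohort generation."""

    n_lesional_sites: int = 2
    n_uninvolved_sites: int = 2
    duration_range: tuple[int, int] = (16, 38)
    lesional_k_range: tuple[float, float] = (1.0, 1.5)
    uninvolved_k_range: tuple[float, float] = (0.12, 0.18)
    em1_rel_sd: float = 0.05
    dose_volume_ml: float = 50.0
    dose_purity: float = 0.70
    doses_per_day: int = 2
    body_water: BodyWaterParams = field(default_factory=BodyWaterParams)
    tewl_lesional_mean: float = 25.0
    tewl_uninvolved_mean: float = 8.0
    tewl_site_rel_sd: float = 0.08
    tewl_reading_rel_sd: float = 0.15
    sampling_day_menu: tuple[int, ...] = SAMPLING_DAY_MENU

    def __post_init__(self) -> None:
        if self.n_lesional_sites < 1 or self.n_uninvolved_sites < 1:
            raise InvalidInputError("each subject needs >= 1 site per group")
        lo, hi = self.duration_range
        if not 1 <= lo <= hi <= 365:
            raise InvalidInputError("invalid duration_range")
        for name, (a, b) in (
            ("lesional_k_range", self.lesional_k_range),
            ("uninvolved_k_range", self.uninvolved_k_range),
        ):
            if not 0 < a <= b:
                raise InvalidInputError(f"invalid {name}")
        if self.em1_rel_sd < 0:
            raise InvalidInputError("em1_rel_sd must be >= 0")
        if self.tewl_lesional_mean <= self.tewl_uninvolved_mean:
            raise InvalidInputError("lesional TEWL mean must exceed non-lesional")
        if lo < max(self.sampling_day_menu[:2]):
            raise InvalidInputError("duration too short for the sampling menu")


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: the tables every pipeline stage consumes,
    plus the generating truth."""

    dosing: pd.DataFrame
    saliva: pd.DataFrame
    tape_strips: pd.DataFrame
    tewl: pd.DataFrame
    spectral: Mapping[str, SpectralCountTable]
    truth: dict


def _sampling_days(duration: int, menu: tuple[int, ...]) -> list[int]:
    days = [d for d in menu if d <= duration]
    # close the series at end of study when the gap keeps a >= 2-day cadence
    if duration - days[-1] >= 2:
        days.append(duration)
    return days


def _draw_lag(
    rng: np.random.Generator,
    sampling_days: list[int],
    window: tuple[float, float],
    k: float,
    tau_floor: float,
    threshold: float = DEFAULT_APPEARANCE_THRESHOLD,
) -> tuple[float, int]:
    """Draw (tau, appearance_day) so that detection first occurs on a sampling
    day inside ``window`` and tau sits on the quarter-day lattice strictly
    after both the preceding sampling day and ``tau_floor``.

    The appearance day must precede the final sampling day: with a single
    post-onset observation the (tau, k) pair lies on a ridge and is not
    estimable, so generated truth is kept observable by design."""
    candidates = [
        d for d in sampling_days[:-1] if window[0] <= d <= window[1]
    ]
    if not candidates:
        raise InvalidInputError(f"no sampling day inside window {window}")
    appearance = int(rng.choice(candidates))
    prev = max([0] + [d for d in sampling_days if d < appearance])
    # f(appearance) > threshold requires appearance - tau > -ln(1-threshold)/k
    margin = -np.log1p(-threshold) / k
    hi = appearance - max(TAU_LATTICE, np.ceil(margin / TAU_LATTICE) * TAU_LATTICE)
    lo = max(prev, tau_floor) + TAU_LATTICE
    lattice = np.arange(lo, hi + 1e-9, TAU_LATTICE)
    if lattice.size == 0:
        raise InvalidInputError(
            f"empty lag lattice for appearance day {appearance} (floor {tau_floor})"
        )
    return float(rng.choice(lattice)), appearance


def _sample_spectral(
    rng: np.random.Generator, condition: str
) -> SpectralCountTable:
    """Multinomial resample of the bundled pilot table's count proportions."""
    ref = load_reference_table(condition)
    totals = np.array([r.total_peptide_count for r in ref.records])
    counts = rng.multinomial(int(totals.sum()), totals / totals.sum())
    records = []
    for rec, c in zip(ref.records, counts):
        if c == 0:
            continue
        records.append(
            SpectralCountRecord(
                protein_name=rec.protein_name,
                unique_peptides=min(rec.unique_peptides, int(c)),
                total_peptide_count=int(c),
                mol_wt=rec.mol_wt,
            )
        )
    return SpectralCountTable(condition=condition, records=tuple(records))


def generate_cohort(
    n_subjects: int = 4,
    seed: int = 0,
    config: CohortConfig | None = None,
    model: LabelingModel | None = None,
    formula: ElementalFormula = DEFAULT_ANALYTE,
) -> CohortBundle:
    """Generate a seeded synthetic cohort.

    Each subject gets a dosing duration drawn from 16-38 days, two lesional
    and two uninvolved sites with recorded (tau, k) truth, saliva enrichment
    on every tape-strip day, EM1 series with multiplicative Gaussian noise
    (negative draws clamped to 0), and duplicate TEWL readings.  EM1 truth is
    computed through the measured-saliva pathway (interpolated curve ->
    time-averaged enrichment -> EM1max x f), so a zero-noise bundle analyzed
    by the pipeline reproduces the generating f exactly.
    """
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be >= 1")
    if config is None:
        config = CohortConfig()
    if model is None:
        model = default_labeling_model()
    rng = np.random.default_rng(seed)

    dosing_rows, saliva_rows, tape_rows, tewl_rows = [], [], [], []
    site_truth: list[dict] = []
    subject_truth: dict[str, dict] = {}

    for s in range(1, n_subjects + 1):
        subject = f"S{s:02d}"
        duration = int(rng.integers(config.duration_range[0], config.duration_range[1] + 1))
        schedule = build_protocol_schedule(
            duration,
            dose_volume_ml=config.dose_volume_ml,
            purity=config.dose_purity,
            doses_per_day=config.doses_per_day,
        )
        for event in schedule.events:
            dosing_rows.append(
                {"subject_id": subject, "day": event.day,
                 "volume_ml": event.volume_ml, "purity": event.purity}
            )
        days = _sampling_days(duration, config.sampling_day_menu)
        sim = simulate_body_water(schedule, config.body_water)
        saliva_vals = sim.value_at(np.array(days, dtype=float))
        for d, v in zip(days, saliva_vals):
            saliva_rows.append(
                {"subject_id": subject, "day": float(d), "enrichment_fraction": float(v)}
            )
        curve = interpolate_measured(zip(map(float, days), saliva_vals))
        p_bar = {d: time_averaged_enrichment(curve, d) for d in days}
        plateau = {d: em1_max(p_bar[d], model, formula) for d in days}

        subject_truth[subject] = {"duration_days": duration, "sampling_days": days}

        site_specs: list[tuple[str, bool]] = []
        for j in range(config.n_lesional_sites):
            site_specs.append((f"L{j + 1}", True))
        for j in range(config.n_uninvolved_sites):
            site_specs.append((f"U{j + 1}", False))

        lesional_tau_max = 0.0
        for site, lesional in site_specs:
            if lesional:
                k = float(rng.uniform(*config.lesional_k_range))
                tau, appearance = _draw_lag(rng, days, LESIONAL_WINDOW, k, tau_floor=0.0)
                lesional_tau_max = max(lesional_tau_max, tau)
            else:
                k = float(rng.uniform(*config.uninvolved_k_range))
                tau, appearance = _draw_lag(
                    rng, days, UNINVOLVED_WINDOW, k, tau_floor=lesional_tau_max
                )
            site_truth.append(
                {"subject_id": subject, "site_id": site, "lesional": lesional,
                 "tau": tau, "k": k, "appearance_day": appearance}
            )
            for d in days:
                em1 = plateau[d] * predict_f(float(d), tau, k)
                if config.em1_rel_sd > 0:
                    em1 *= 1.0 + rng.normal(0.0, config.em1_rel_sd)
                tape_rows.append(
                    {"subject_id": subject, "site_id": site,
                     "lesional": int(lesional), "day": float(d),
                     "em1": max(em1, 0.0)}
                )
            group_mean = (config.tewl_lesional_mean if lesional
                          else config.tewl_uninvolved_mean)
            site_mean = group_mean * max(
                1.0 + rng.normal(0.0, config.tewl_site_rel_sd), 0.2
            )
            for d in days:
                readings = site_mean * np.maximum(
                    1.0 + rng.normal(0.0, config.tewl_reading_rel_sd, size=2), 0.05
                )
                tewl_rows.append(
                    {"subject_id": subject, "site_id": site,
                     "lesional": int(lesional), "day": float(d),
                     "reading_1": float(readings[0]), "reading_2": float(readings[1])}
                )

    spectral = {
        "uninvolved": _sample_spectral(rng, "uninvolved"),
        "psoriatic": _sample_spectral(rng, "psoriatic"),
    }
    truth = {
        "seed": int(seed),
        "em1_rel_sd": config.em1_rel_sd,
        "labeling_model": {
            "n_sites": model.n_sites,
            "site_exchange_fraction": model.site_exchange_fraction,
        },
        "subjects": subject_truth,
        "sites": site_truth,
    }
    return CohortBundle(
        dosing=pd.DataFrame(dosing_rows),
        saliva=pd.DataFrame(saliva_rows),
        tape_strips=pd.DataFrame(tape_rows),
        tewl=pd.DataFrame(tewl_rows),
        spectral=spectral,
        truth=truth,
    )


def truth_report(bundle: CohortBundle) -> pd.DataFrame:
    """Machine-readable generating parameters: one row per site."""
    sites = bundle.truth.get("sites", [])
    df = pd.DataFrame(
        sites, columns=["subject_id", "site_id", "lesional", "tau", "k", "appearance_day"]
    )
    df["em1_rel_sd"] = bundle.truth.get("em1_rel_sd", np.nan) if len(df) else np.nan
    return df
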