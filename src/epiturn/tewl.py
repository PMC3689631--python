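"""Transepidermal water loss (TEWL) summaries and lesional contrasts.

TEWL (g m^-2 h^-1) measures water flux through the skin barrier with an
evaporimeter; elevated values indicate impaired barrier function.  Readings
are taken in duplicate per site and day and reported as mean +/- SD.  Only
descriptive contrasts are computed — per-subject lesional minus non-lesional
differences on shared days, a cohort sign count, and per-site day-to-day
coefficients of variation (TEWL is notoriously noisy across days) — no
formal hypothesis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InvalidInputError

__all__ = ["TEWLRecord", "TEWLSummary", "summarize_tewl", "lesional_contrast"]


@dataclass(frozen=True)
class TEWLRecord:
    """Evaporimeter readings for one site on one day."""

    subject_id: str
    site_id: str
    lesional: bool
    day: float
    readings: tuple[float, ...]

    def __post_init__(self) -> None:
        readings = tuple(float(r) for r in self.readings)
        if not readings:
            raise InvalidInputError("readings must be non-empty")
        if any(r <= 0 for r in readings):
            raise InvalidInputError("TEWL readings must be positive")
        object.__setattr__(self, "readings", readings)


@dataclass(frozen=True)
class TEWLSummary:
    """Mean and sample SD of one record's readings."""

    mean: float
    sd: float
    n_readings: int
    single_reading: bool


def summarize_tewl(record: TEWLRecord) -> TEWLSummary:
    """Arithmetic mean and sample SD of the duplicate readings.

    SD is 0 (flagged) when only a single reading exists.
    """
    values = np.asarray(record.readings)
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return TEWLSummary(mean=float(values.mean()), sd=sd, n_readings=n,
                       single_reading=n == 1)


def _per_day_group_means(records: list[TEWLRecord]) -> dict[float, float]:
    """Mean of site-level means per day, for one subject-group."""
    by_day: dict[float, list[float]] = {}
    for rec in records:
        by_day.setdefault(rec.day, []).append(summarize_tewl(rec).mean)
    return {day: float(np.mean(means)) for day, means in by_day.items()}


def _site_cv(records: list[TEWLRecord]) -> dict[str, float]:
    """Day-to-day coefficient of variation of each site's daily means."""
    by_site: dict[str, list[float]] = {}
    for rec in records:
        by_site.setdefault(rec.site_id, []).append(summarize_tewl(rec).mean)
    out = {}
    for site, means in by_site.items():
        if len(means) >= 2:
            arr = np.asarray(means)
            out[site] = float(arr.std(ddof=1) / arr.mean())
    return out


def lesional_contrast(records: Iterable[TEWLRecord]) -> dict:
    """Per-subject paired lesional vs non-lesional TEWL contrast.

    For each subject with both groups measured, the difference of group
    means (lesional minus non-lesional, averaging site means per day) over
    the days shared by both groups.  Subjects lacking either group or any
    shared day are excluded with a warning.  Also reports the cohort count
    of positive differences and per-site day-to-day CVs.
    """
    by_subject: dict[str, dict[bool, list[TEWLRecord]]] = {}
    all_records = list(records)
    for rec in all_records:
        by_subject.setdefault(rec.subject_id, {True: [], False: []})[rec.lesional].append(rec)

    subjects: dict[str, dict] = {}
    excluded: list[str] = []
    for subject, groups in sorted(by_subject.items()):
        if not groups[True] or not groups[False]:
            warnings.warn(f"subject {subject}: unpaired (missing a group); excluded",
                          stacklevel=2)
            excluded.append(subject)
            continue
        les = _per_day_group_means(groups[True])
        non = _per_day_group_means(groups[False])
        shared = sorted(set(les) & set(non))
        if not shared:
            warnings.warn(f"subject {subject}: no shared measurement days; excluded",
                          stacklevel=2)
            excluded.append(subject)
            continue
        diffs = [les[d] - non[d] for d in shared]
        subjects[subject] = {
            "shared_days": shared,
            "mean_difference": float(np.mean(diffs)),
            "per_day_difference": {d: float(les[d] - non[d]) for d in shared},
            "lesional_mean": float(np.mean([les[d] for d in shared])),
            "non_lesional_mean": float(np.mean([non[d] for d in shared])),
            "site_cv": _site_cv(groups[True] + groups[False]),
        }
    return {
        "subjects": subjects,
        "excluded_subjects": excluded,
        "n_subjects": len(subjects),
        "n_positive": sum(1 for s in subjects.values() if s["mean_difference"] > 0),
    }
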