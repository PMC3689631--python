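"""End-to-end analysis: tape-strip tables -> per-site conveyor fits and
cohort summaries, with optional diagnostic plots."""

from __future__ import annotations

import json
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .body_water import interpolate_measured
from .errors import InsufficientDataError, InvalidInputError
from .isotopomers import (
    ElementalFormula,
    calibrate_labeling_model,
)
from .kinetics import (
    SiteFit,
    TapeStripSeries,
    appearance_time,
    compare_sites,
    fit_conveyor,
    predict_f,
    series_to_f,
)
from .proteomics import SpectralCountTable, rank_by_abundance, summarize_table
from .tewl import lesional_contrast

__all__ = ["analyze_cohort", "proteomics_summary", "tewl_summary", "assemble_report"]


def _site_seed(base: int, index: int) -> int:
    # distinct, reproducible per-site bootstrap seeds below 2**31
    return (int(base) * 1_000_003 + 7919 * index) % (2**31 - 1)


def analyze_cohort(config: eio.RunConfig, plots: bool = False) -> dict:
    """Run the kinetic pipeline on a cohort directory.

    Per subject, the measured-saliva curve is interpolated; per site, EM1 is
    converted to fractional synthesis and the delayed-rise model is fitted.
    Writes ``fits.csv``, ``summary.json`` and a manifest to the output
    directory; returns the summary.
    """
    bundle = eio.read_cohort(config.input_dir)
    model = calibrate_labeling_model(
        target_amplification=config.amplification,
        n_sites=config.n_label_sites,
        formula=ElementalFormula(config.analyte_formula),
    )
    formula = ElementalFormula(config.analyte_formula)

    curves = {}
    for subject, grp in bundle.saliva.groupby("subject_id"):
        curves[subject] = interpolate_measured(
            zip(grp["day"].astype(float), grp["enrichment_fraction"].astype(float))
        )

    site_fits: list[SiteFit] = []
    rows = []
    plots_data = []
    for index, ((subject, site), grp) in enumerate(
        sorted(bundle.tape_strips.groupby(["subject_id", "site_id"]))
    ):
        if subject not in curves:
            warnings.warn(f"{subject}/{site}: no saliva curve; skipped", stacklevel=2)
            continue
        grp = grp.sort_values("day")
        lesional = bool(int(grp["lesional"].iloc[0]))
        series = TapeStripSeries(
            subject_id=str(subject),
            site_id=str(site),
            lesional=lesional,
            days=grp["day"].to_numpy(float),
            em1=grp["em1"].to_numpy(float),
            curve=curves[subject],
        )
        points, skipped = series_to_f(series, model, formula)
        if len(points) < 3:
            warnings.warn(
                f"{subject}/{site}: fewer than 3 usable points; skipped", stacklevel=2
            )
            continue
        fit_cfg = replace(config.fit, seed=_site_seed(config.seed, index))
        fit = fit_conveyor(points, fit_cfg)
        onset = appearance_time(points, config.appearance_threshold)
        site_fits.append(SiteFit(str(subject), str(site), lesional, fit))
        rows.append(
            {
                "subject_id": subject,
                "site_id": site,
                "lesional": int(lesional),
                "tau": fit.tau,
                "tau_ci_low": fit.tau_ci[0],
                "tau_ci_high": fit.tau_ci[1],
                "k": fit.k,
                "k_ci_low": fit.k_ci[0],
                "k_ci_high": fit.k_ci[1],
                "rss": fit.rss,
                "n_points": fit.n_points,
                "appearance_day": onset if onset is not None else np.nan,
                "appearance_censored": int(onset is None),
                "n_skipped_points": len(skipped),
                "flags": ";".join(fit.flags),
            }
        )
        plots_data.append((series, points, fit))

    if not site_fits:
        raise InsufficientDataError(f"no analyzable sites under {config.input_dir}")
    summary = {"sites": compare_sites(site_fits), "n_sites": len(site_fits)}
    if len(bundle.tewl):
        tewl_records = eio.read_tewl(Path(config.input_dir) / eio.TEWL_FILE)
        summary["tewl"] = lesional_contrast(tewl_records)
    if bundle.spectral:
        summary["proteomics"] = {
            condition: summarize_table(table)
            for condition, table in sorted(bundle.spectral.items())
        }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    eio.write_manifest(out, config.to_dict(), config.seed)
    if plots:
        _plot_sites(plots_data, curves, model, out / "plots")
    return summary


def _plot_sites(plots_data, curves, model, plot_dir: Path) -> None:
    """Per-subject overlay: site f(t) points and fits, plus the body-water
    curve scaled by the labeling amplification (the expected plateau track)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list] = {}
    for series, points, fit in plots_data:
        by_subject.setdefault(series.subject_id, []).append((series, points, fit))
    for subject, entries in sorted(by_subject.items()):
        fig, ax = plt.subplots(figsize=(6, 4))
        curve = curves[subject]
        ax.plot(curve.days, curve.values / max(curve.values.max(), 1e-12),
                "k--", lw=0.8, label="body water (scaled)")
        tt = np.linspace(0, curve.days[-1], 200)
        for series, points, fit in entries:
            color = "C3" if series.lesional else "C0"
            ax.plot([p.day for p in points], [p.f for p in points], "o",
                    color=color, ms=4,
                    label=f"{series.site_id} ({'lesional' if series.lesional else 'uninvolved'})")
            ax.plot(tt, predict_f(tt, fit.tau, fit.k), "-", color=color, lw=1)
        ax.set_xlabel("days since labeling start")
        ax.set_ylabel("fractional synthesis f")
        ax.set_title(f"subject {subject}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_dir / f"{subject}.png", dpi=120)
        plt.close(fig)


def proteomics_summary(table_path: str | Path, condition: str, out_dir: str | Path | None = None) -> dict:
    """Rank a spectral-count table and summarize its keratin fraction."""
    table = SpectralCountTable.from_tsv(table_path, condition=condition)
    ranked = rank_by_abundance(table)
    summary = summarize_table(table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked.to_dataframe().to_csv(out / f"ranked_{condition}.tsv", sep="\t", index=False)
        with open(out / f"proteomics_{condition}.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def tewl_summary(table_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Summarize a TEWL table: per-subject lesional contrasts and site CVs."""
    records = eio.read_tewl(table_path)
    summary = lesional_contrast(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "tewl_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary


def assemble_report(results_dir: str | Path) -> dict:
    """Collect the JSON summaries under a results directory into one report."""
    results_dir = Path(results_dir)
    report: dict = {}
    for name in ("summary.json", "tewl_summary.json"):
        p = results_dir / name
        if p.exists():
            with open(p) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    for p in sorted(results_dir.glob("proteomics_*.json")):
        with open(p) as fh:
            report[p.stem] = json.load(fh)
    if not report:
        raise InvalidInputError(f"no summaries found under {results_dir}")
    with open(results_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
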