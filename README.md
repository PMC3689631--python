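# epiturn

Heavy-water (²H₂O) labeling analysis of epidermal protein turnover from
tape-strip mass-isotopomer data.

## The problem

Psoriatic plaques turn over their epidermis dramatically faster than healthy
skin, but classical kinetic measurements need biopsies or radioactive
tracers. A non-invasive alternative: subjects drink small doses of heavy
water (50 mL of 70% ²H₂O twice daily, Monday–Friday, for 16–38 days);
deuterium equilibrates into the body water and into the carbon-bound
hydrogens of free alanine, so newly synthesized protein carries excess
mass-1 isotopologues. Serial adhesive tape strips sample the stratum corneum
surface; GC/MS on protein-bound alanine (as its pentafluorobenzyl
derivative) reads out the labeling, and the delay between body-water
enrichment and surface label appearance measures the epidermal transit time.

`epiturn` implements this analysis end to end for cohorts of lesional and
uninvolved skin sites, plus the accompanying spectral-count proteomics and
transepidermal water loss (TEWL) summaries, and a seeded synthetic-cohort
generator so the whole pipeline is testable without any subject data.

## The model

**Labeling readout.** EM1 is the molar fraction of analyte molecules one
nominal mass unit above monoisotopic, in excess of natural abundance.
Isotopologue distributions are computed by per-element polynomial
convolution of standard terrestrial isotope abundances; a 100%-new
population adds a binomial label term over the *n* = 4 alanine C–H
positions, each exchanging with body water with probability *c* (the
site-exchange fraction). At tracer-level body-water enrichment *p*, the
plateau excess EM1max(*p*) ≈ *A·p* with amplification *A* = 2.7, the
empirical body-water→alanine correlation to which the default model is
calibrated.

**Fractional synthesis.** For a tape strip at day *t*,

    f(t) = EM1(t) / EM1max(p̄(t)),

where p̄(t) is the time-averaged body-water enrichment from the start of
labeling (measured in saliva and interpolated, or forward-simulated with a
one-compartment dosing model).

**Conveyor kinetics.** The stratum corneum is modeled as a conveyor with
transit lag τ and first-order surface replacement rate k:

    f(t) = 0                        t ≤ τ
    f(t) = 1 − exp(−k (t − τ))      t > τ

Each site is fitted by least squares (τ on a 0.25-day grid, k by profiled
1-D minimization) with seeded bootstrap confidence intervals. Lesional
psoriatic sites show label within 3–8 days and near-100% newly synthesized
protein; uninvolved sites lag 10–20 days.

**Proteomics and TEWL.** Spectral-count tables are ranked by the abundance
index (total peptide count / molecular weight × 10³) and summarized by their
keratin-derived count fraction (~98% in uninvolved stratum corneum). TEWL
duplicate readings are summarized as mean ± SD with per-subject lesional
minus non-lesional contrasts.

## Worked example

```sh
epiturn simulate --n-subjects 4 --seed 42 --out demo/cohort
epiturn analyze  --inputs demo/cohort --out demo/results --n-boot 100 --seed 1
epiturn proteomics --table demo/cohort/spectral_counts_uninvolved.tsv \
                   --condition uninvolved --out demo/results
epiturn tewl --table demo/cohort/tewl.csv --out demo/results
epiturn report --results demo/results
```

prints

```
wrote cohort (4 subjects) to demo/cohort
lesional: median tau 7.50 d over 8 sites; uninvolved: median tau 14.25 d over 8 sites
results written to demo/results
{
 "condition": "uninvolved",
 "keratin_percent": 98,
 ...
 "top_protein": "Keratin 10"
}
4/4 subjects with lesional > non-lesional TEWL
wrote demo/results/report.json
```

The simulated cohort of 4 subjects (2 lesional + 2 uninvolved sites each,
5% relative EM1 noise) yields a lesional median transit lag of 7.5 days vs
14.25 days for uninvolved skin — the fast-vs-slow contrast the labeling
method is designed to detect — with replacement rates near 1–7/day
(lesional, mostly a lower bound once the rise saturates) vs ~0.16/day
(uninvolved). `demo/results/fits.csv` holds per-site τ and k with bootstrap
CIs and flags; `summary.json` the group medians, ranges and within-subject
spreads; the bundled spectral-count table summarizes to 98% keratin with
Keratin 10 ranked first.

The same analysis runs on real data: put `saliva.csv`, `tape_strips.csv`
(and optionally `tewl.csv`, spectral-count TSVs) in a directory using the
column layouts written by `simulate`, and point `epiturn analyze` at it.

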