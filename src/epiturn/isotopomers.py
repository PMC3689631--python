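"""Mass-isotopomer distributions for heavy-water labeling readouts.

The labeling readout used throughout this package is EM1: the molar fraction
of analyte molecules one nominal mass unit above monoisotopic, in excess of
the natural-abundance M1 fraction.  During ``2H2O`` labeling, deuterium from
body water equilibrates into the carbon-bound hydrogens of free alanine
before protein synthesis; protein-bound alanine from newly synthesized
protein therefore carries excess M1 (and higher) isotopologues, while
pre-existing protein sits at natural abundance.  Because several hydrogen
positions can carry label, the M1 excess of a fully new population is an
*amplified* multiple of the body-water enrichment itself — empirically a
factor of 2.7 at tracer-level enrichments for the alanine analyte, which is
how the default labeling model is calibrated.

Distributions are computed by per-element polynomial convolution of
single-atom isotope-abundance vectors, truncated at a configurable mass
order.  The analyte default is the pentafluorobenzyl derivative of alanine
(C10H8F5NO2) measured by NCI-GC/MS; any elemental formula can be substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import DomainError, InvalidInputError

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "MAX_PRECURSOR_ENRICHMENT",
    "DEFAULT_TRUNCATION_ORDER",
    "DEFAULT_AMPLIFICATION",
    "ALANINE",
    "PFB_ALANINE",
    "DEFAULT_ANALYTE",
    "ElementalFormula",
    "IsotopomerDistribution",
    "LabelingModel",
    "natural_abundance_distribution",
    "labeled_distribution",
    "em1_excess",
    "em1_max",
    "calibrate_labeling_model",
    "default_labeling_model",
]

#: IUPAC representative terrestrial isotopic abundances, as mole fractions
#: indexed by nominal mass shift above the lightest isotope of each element.
#: (H: 1H/2H; C: 12C/13C; N: 14N/15N; O: 16O/17O/18O; S: 32/33/34/-/36; etc.)
ISOTOPE_ABUNDANCES: Mapping[str, tuple[float, ...]] = MappingProxyType({
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Cl": (0.7576, 0.0, 0.2424),
    "Br": (0.5069, 0.0, 0.4931),
})

#: Body-water enrichment can never exceed the purity of the administered dose.
MAX_PRECURSOR_ENRICHMENT = 0.70

#: Distributions are computed to M4 by default: EM1 only needs M0/M1, and the
#: truncation error at M4 is far below GC/MS measurement noise.
DEFAULT_TRUNCATION_ORDER = 4

#: Low-enrichment ratio of plateau alanine EM1 to body-water 2H enrichment;
#: the empirical body-water -> alanine amplification the default model is
#: calibrated to.
DEFAULT_AMPLIFICATION = 2.7

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of the measured analyte.

    Parameters
    ----------
    counts
        Mapping element symbol -> atom count.  All counts must be
        non-negative integers and at least one atom must be present.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in ISOTOPE_ABUNDANCES:
                raise InvalidInputError(f"unknown element {element!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise InvalidInputError(f"count for {element!r} must be a non-negative integer")
            if n > 0:
                clean[element] = int(n)
        if not clean:
            raise InvalidInputError("formula must contain at least one atom")
        object.__setattr__(self, "counts", MappingProxyType(clean))

    @classmethod
    def from_string(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C10H8F5NO2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise InvalidInputError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element = match.group(1)
            n = int(match.group(2)) if match.group(2) else 1
            counts[element] = counts.get(element, 0) + n
        if pos != len(formula) or not counts:
            raise InvalidInputError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)


#: Free alanine.
ALANINE = ElementalFormula.from_string("C3H7NO2")
#: Pentafluorobenzyl ester of alanine, the derivatized analyte measured by
#: NCI-GC/MS.  The monitored fragment's exact composition is an assumption of
#: this package and is configurable per run.
PFB_ALANINE = ElementalFormula.from_string("C10H8F5NO2")
DEFAULT_ANALYTE = PFB_ALANINE


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Mole fractions of the M0..Mk nominal-mass isotopologues of an analyte."""

    fractions: tuple[float, ...]
    truncation_order: int

    def __post_init__(self) -> None:
        fr = tuple(float(x) for x in self.fractions)
        if self.truncation_order < 1:
            raise InvalidInputError("truncation_order must be >= 1")
        if len(fr) != self.truncation_order + 1:
            raise InvalidInputError("fractions must have truncation_order + 1 entries")
        if any(x < -1e-12 or x > 1 + 1e-12 for x in fr):
            raise InvalidInputError("fractions must lie in [0, 1]")
        if sum(fr) > 1 + 1e-9:
            raise InvalidInputError("fractions must sum to at most 1")
        object.__setattr__(self, "fractions", fr)

    @property
    def m0(self) -> float:
        return self.fractions[0]

    @property
    def m1(self) -> float:
        return self.fractions[1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions)


@dataclass(frozen=True)
class LabelingModel:
    """Deuterium-incorporation model for the alanine analyte.

    ``n_sites`` carbon-bound hydrogen positions can acquire label; each
    equilibrates with body water with probability ``site_exchange_fraction``.
    The product of the two (times the M0/M1 structure of the remaining atoms)
    sets the low-enrichment amplification of EM1 over body-water enrichment.
    """

    n_sites: int = 4
    site_exchange_fraction: float = 0.675

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidInputError("n_sites must be >= 1")
        if not 0.0 <= self.site_exchange_fraction <= 1.0:
            raise InvalidInputError("site_exchange_fraction must lie in [0, 1]")

    def amplification(self, formula: ElementalFormula = DEFAULT_ANALYTE) -> float:
        """Low-enrichment limit of em1_max(p)/p for this model and analyte."""
        p = 1e-6
        return em1_max(p, self, formula) / p


def _truncated_convolve(a: np.ndarray, b: np.ndarray, order: int) -> np.ndarray:
    return np.convolve(a, b)[: order + 1]


def _element_polynomial(element: str, n_atoms: int, order: int) -> np.ndarray:
    """Isotopologue mass-shift polynomial of ``n_atoms`` atoms of one element."""
    single = np.asarray(ISOTOPE_ABUNDANCES[element])[: order + 1]
    poly = np.array([1.0])
    for _ in range(n_atoms):
        poly = _truncated_convolve(poly, single, order)
    return poly


def _natural_polynomial(counts: Mapping[str, int], order: int) -> np.ndarray:
    poly = np.array([1.0])
    for element, n in counts.items():
        if n:
            poly = _truncated_convolve(poly, _element_polynomial(element, n, order), order)
    out = np.zeros(order + 1)
    out[: len(poly)] = poly
    return out


def _as_distribution(poly: np.ndarray, order: int) -> IsotopomerDistribution:
    padded = np.zeros(order + 1)
    padded[: len(poly)] = np.clip(poly, 0.0, 1.0)
    return IsotopomerDistribution(tuple(padded), order)


def natural_abundance_distribution(
    formula: ElementalFormula,
    truncation_order: int = DEFAULT_TRUNCATION_ORDER,
) -> IsotopomerDistribution:
    """Natural-abundance isotopologue distribution of ``formula``.

    Computed from standard terrestrial isotope abundances by per-element
    polynomial convolution, truncated at ``M(truncation_order)``.
    """
    if truncation_order < 1:
        raise InvalidInputError("truncation_order must be >= 1")
    poly = _natural_polynomial(formula.counts, truncation_order)
    return _as_distribution(poly, truncation_order)


def _check_enrichment(p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= MAX_PRECURSOR_ENRICHMENT:
        raise DomainError(
            f"precursor enrichment must lie in [0, {MAX_PRECURSOR_ENRICHMENT}], got {p}"
        )
    return p


def labeled_distribution(
    formula: ElementalFormula,
    model: LabelingModel,
    p: float,
    truncation_order: int = DEFAULT_TRUNCATION_ORDER,
    natural_abundance: bool = True,
) -> IsotopomerDistribution:
    """Isotopologue distribution of a 100%-newly-synthesized analyte population.

    Label incorporation is binomial across the model's ``n_sites`` hydrogen
    positions.  A given site exchanges with body water with probability
    ``site_exchange_fraction * p``; otherwise it retains the natural 2H
    abundance, so the labeled sites' natural deuterium contribution is
    replaced by the labeling term rather than double-counted.  The remaining
    atoms contribute their natural-abundance polynomial (disabled when
    ``natural_abundance`` is False, which isolates the pure labeling binomial
    for validation).
    """
    p = _check_enrichment(p)
    if truncation_order < 1:
        raise InvalidInputError("truncation_order must be >= 1")
    n_h = formula["H"]
    if n_h < model.n_sites:
        raise InvalidInputError(
            f"formula has {n_h} hydrogens but the model labels {model.n_sites} sites"
        )
    a2h = ISOTOPE_ABUNDANCES["H"][1] if natural_abundance else 0.0
    exchange = model.site_exchange_fraction * p
    q = exchange + a2h * (1.0 - exchange)  # per-site 2H probability

    k = truncation_order
    n = model.n_sites
    site_poly = np.array(
        [comb(n, j) * q**j * (1.0 - q) ** (n - j) for j in range(min(n, k) + 1)]
    )

    rest_counts = {el: cnt for el, cnt in formula.counts.items()}
    rest_counts["H"] = n_h - n
    if natural_abundance:
        rest_poly = _natural_polynomial(rest_counts, k)
    else:
        rest_poly = np.array([1.0])
    poly = _truncated_convolve(site_poly, rest_poly, k)
    return _as_distribution(poly, k)


def em1_excess(
    measured: IsotopomerDistribution, baseline: IsotopomerDistribution
) -> float:
    """M1 fraction of ``measured`` minus M1 of ``baseline`` (EM1).

    Not clamped: noisy measured input may yield slightly negative values;
    clamping is a kinetics-layer decision.
    """
    if measured.truncation_order != baseline.truncation_order:
        raise InvalidInputError("distributions must share a truncation order")
    return measured.m1 - baseline.m1


def em1_max(
    p_bar: float,
    model: LabelingModel,
    formula: ElementalFormula = DEFAULT_ANALYTE,
    truncation_order: int = DEFAULT_TRUNCATION_ORDER,
) -> float:
    """EM1 of a fully newly synthesized population at precursor enrichment ``p_bar``."""
    labeled = labeled_distribution(formula, model, p_bar, truncation_order)
    baseline = natural_abundance_distribution(formula, truncation_order)
    return em1_excess(labeled, baseline)


def calibrate_labeling_model(
    target_amplification: float = DEFAULT_AMPLIFICATION,
    n_sites: int = 4,
    formula: ElementalFormula = DEFAULT_ANALYTE,
) -> LabelingModel:
    """Solve the site-exchange fraction so the low-enrichment EM1max/p limit
    equals ``target_amplification`` for the given analyte.

    The limit is linear in the exchange fraction at tracer-level enrichment,
    so a single probe evaluation at full exchange suffices.
    """
    if target_amplification <= 0:
        raise InvalidInputError("target_amplification must be positive")
    probe = LabelingModel(n_sites=n_sites, site_exchange_fraction=1.0)
    slope = probe.amplification(formula)
    fraction = target_amplification / slope
    if not 0.0 < fraction <= 1.0:
        raise InvalidInputError(
            f"target amplification {target_amplification} not attainable with "
            f"{n_sites} sites (requires exchange fraction {fraction:.3f})"
        )
    return LabelingModel(n_sites=n_sites, site_exchange_fraction=fraction)


@lru_cache(maxsize=None)
def default_labeling_model() -> LabelingModel:
    """Default model: 4 alanine C-H sites, exchange fraction calibrated so the
    low-enrichment EM1max/p ratio equals 2.7 for the default analyte."""
    return calibrate_labeling_model()
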