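"""Shared fixtures: labeling model, synthetic cohorts, enumeration oracle."""

from __future__ import annotations

from itertools import product
from math import comb, factorial, prod

import numpy as np
import pytest

from epiturn.isotopomers import (
    ISOTOPE_ABUNDANCES,
    ElementalFormula,
    default_labeling_model,
)
from epiturn.synthetic import CohortConfig, generate_cohort


def _compositions(n: int, parts: int):
    """All ways to split n atoms over `parts` isotope slots."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def enumerate_natural_distribution(formula: ElementalFormula, order: int) -> np.ndarray:
    """Exhaustive enumeration oracle for the natural isotopologue distribution.

    Enumerates every isotope composition of every element (multinomial
    probabilities, explicit mass shifts) and takes the cartesian product
    across elements — an independent path from the package's polynomial
    convolution.
    """
    per_element = []
    for element, n in formula.counts.items():
        abund = ISOTOPE_ABUNDANCES[element]
        options = []
        for split in _compositions(n, len(abund)):
            prob = factorial(n)
            for count, a in zip(split, abund):
                prob = prob * a**count / factorial(count)
            shift = sum(i * count for i, count in enumerate(split))
            if prob > 0:
                options.append((shift, prob))
        per_element.append(options)
    dist = np.zeros(order + 1)
    for combo in product(*per_element):
        shift = sum(s for s, _ in combo)
        if shift <= order:
            dist[shift] += prod(p for _, p in combo)
    return dist


def enumerate_labeled_distribution(
    formula: ElementalFormula, n_sites: int, q: float, order: int
) -> np.ndarray:
    """Enumeration oracle for a labeled population: explicit binomial over the
    label sites convolved (by double loop) with the natural oracle of the
    remaining atoms."""
    rest = dict(formula.counts)
    rest["H"] = rest["H"] - n_sites
    rest_formula = ElementalFormula({el: c for el, c in rest.items() if c})
    rest_dist = enumerate_natural_distribution(rest_formula, order)
    dist = np.zeros(order + 1)
    for j in range(n_sites + 1):
        pj = comb(n_sites, j) * q**j * (1 - q) ** (n_sites - j)
        for m, pm in enumerate(rest_dist):
            if j + m <= order:
                dist[j + m] += pj * pm
    return dist


@pytest.fixture(scope="session")
def model():
    return default_labeling_model()


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise 4-subject cohort for closed-loop tests."""
    return generate_cohort(4, seed=11, config=CohortConfig(em1_rel_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise 4-subject cohort."""
    return generate_cohort(4, seed=11)
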