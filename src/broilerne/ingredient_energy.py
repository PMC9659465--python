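"""Substitution-method energy values of single ingredients.

A test diet replaces part of a reference diet's energy-yielding fraction
with one test ingredient. On a DM basis, a% of the test diet is the
reference-origin energy-yielding share and b% is the test-ingredient
share, so any energy value E obeys the mixing rule

    E_test = E_ref * a/100 + E_ingredient * b/100

and the ingredient value is recovered as

    E_ingredient = (E_test - E_ref * a/100) / (b/100).

The study design behind the packaged tables used a = 67.58, b = 31.32
(DM basis); those printed constants are the default scheme, and
:func:`substitution_levels` recomputes a and b from formulations when the
per-ingredient DM values are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .study_io import DietFormulation, DietRole, IngredientComposition

__all__ = [
    "SubstitutionScheme",
    "PRINTED_SCHEME",
    "IngredientEnergyValues",
    "substitution_levels",
    "ingredient_energy",
    "summarize_samples",
    "SummaryStats",
]


@dataclass(frozen=True)
class SubstitutionScheme:
    """DM shares (%) of the test diet: a = reference-origin energy-yielding
    ingredients, b = the test ingredient."""

    a_pct: float
    b_pct: float

    def __post_init__(self) -> None:
        if not (0 < self.a_pct < 100 and 0 < self.b_pct < 100):
            raise ValueError("a_pct and b_pct must be in (0, 100)")
        if self.a_pct + self.b_pct > 100:
            raise ValueError("a_pct + b_pct must not exceed 100")


#: Constants of the packaged study design.
PRINTED_SCHEME = SubstitutionScheme(a_pct=67.58, b_pct=31.32)


@dataclass
class IngredientEnergyValues:
    """Substitution-method energies of one ingredient, MJ/kg DM, with
    utilization ratios in percent (absent when GE is unknown)."""

    ingredient_id: str
    ame: float
    amen: float
    ne: float
    ame_ge: Optional[float] = None
    amen_ge: Optional[float] = None
    ne_ame: Optional[float] = None
    ne_amen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ne_ame is None and self.ame:
            self.ne_ame = 100.0 * self.ne / self.ame
        if self.ne_amen is None and self.amen:
            self.ne_amen = 100.0 * self.ne / self.amen


def substitution_levels(ref: DietFormulation, test: DietFormulation,
                        ingredients: Sequence[IngredientComposition],
                        default_dm: float = 90.0) -> SubstitutionScheme:
    """Recompute the DM-basis substitution shares from formulations.

    Air-dry inclusions are weighted by each ingredient's DM; ingredients
    without a composition record fall back to ``default_dm`` percent DM
    (minor ingredients' DM is rarely assayed). a% sums the reference-origin
    energy-yielding ingredients present in the test diet, b% is the test
    ingredient's share.
    """
    if test.role is not DietRole.test or test.test_ingredient_id is None:
        raise ValueError(f"diet {test.diet_id} is not a test diet")
    dm_by_id = {i.ingredient_id: i.dm for i in ingredients}

    def dm_of(ing: str) -> float:
        return dm_by_id.get(ing, default_dm) / 100.0

    total = sum(pct * dm_of(ing) for ing, pct in test.inclusions)
    if not total > 0:
        raise ValueError("empty test diet")
    ref_energy_ids = ref.energy_yielding_ids or {
        ing for ing, _ in ref.inclusions}
    a = sum(pct * dm_of(ing) for ing, pct in test.inclusions
            if ing in ref_energy_ids and ing != test.test_ingredient_id)
    b = test.inclusion_of(test.test_ingredient_id) * dm_of(
        test.test_ingredient_id)
    return SubstitutionScheme(a_pct=100.0 * a / total,
                              b_pct=100.0 * b / total)


def ingredient_energy(test_ame: float, test_amen: float, test_ne: float,
                      ref_ame: float, ref_amen: float, ref_ne: float,
                      scheme: SubstitutionScheme,
                      ingredient_id: str = "",
                      ge: Optional[float] = None) -> IngredientEnergyValues:
    """Invert the diet mixing rule for AME, AMEn and NE at once.

    ``ge`` (MJ/kg DM of the ingredient), when given, populates the
    AME/GE and AMEn/GE ratios.
    """
    if not scheme.b_pct > 0:
        raise ValueError("b_pct must be positive")
    a, b = scheme.a_pct / 100.0, scheme.b_pct / 100.0

    def invert(e_test: float, e_ref: float) -> float:
        return (e_test - e_ref * a) / b

    ame = invert(test_ame, ref_ame)
    amen = invert(test_amen, ref_amen)
    ne = invert(test_ne, ref_ne)
    vals = IngredientEnergyValues(ingredient_id=ingredient_id,
                                  ame=ame, amen=amen, ne=ne)
    if ge:
        vals.ame_ge = 100.0 * ame / ge
        vals.amen_ge = 100.0 * amen / ge
    return vals


@dataclass
class SummaryStats:
    """Cross-sample summary: mean with (n-1) dispersion measures."""

    n: int
    mean: float
    sd: Optional[float] = None
    cv_pct: Optional[float] = None
    sem: Optional[float] = None
    rsd_pct: Optional[float] = None


def summarize_samples(values: Sequence[float],
                      replicates: Optional[Sequence[Sequence[float]]] = None,
                      ) -> SummaryStats:
    """Mean, SD, CV%, SEM and RSD% of a set of sample-level values.

    With per-sample ``replicates`` supplied, SEM is the pooled one-way
    ANOVA standard error sqrt(MSE / harmonic-mean n) and RSD% the pooled
    within-sample CV; otherwise SEM falls back to sd/sqrt(n) and RSD% to
    the across-sample CV.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no values to summarize")
    mean = float(x.mean())
    if n < 2:
        return SummaryStats(n=n, mean=mean)
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean else math.nan
    if replicates is not None:
        groups = [np.asarray(g, dtype=float) for g in replicates]
        dfs = [g.size - 1 for g in groups]
        if min(g.size for g in groups) < 2:
            raise ValueError("each replicate group needs >= 2 values")
        sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
        mse = sse / sum(dfs)
        n_h = len(groups) / sum(1.0 / g.size for g in groups)
        sem = float(np.sqrt(mse / n_h))
        grand = np.concatenate(groups).mean()
        rsd = 100.0 * math.sqrt(mse) / grand if grand else math.nan
    else:
        sem = sd / math.sqrt(n)
        rsd = cv
    return SummaryStats(n=n, mean=mean, sd=sd, cv_pct=cv, sem=sem,
                        rsd_pct=rsd)
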