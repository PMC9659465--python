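"""Packaged study tables: ingredient compositions, diet formulations and
assays, and the published diet- and ingredient-level energy values.

The tables transcribe the printed results of the underlying feeding
trial (5 wheat and 5 wheat-bran samples evaluated in 12- to 14-day-old
broilers, plus one validation sample of each kind, labelled ``*_v``).
Ingredient gross energy is not assayed directly; where needed it is
back-computed from the published AME and AME/GE ratio.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .ingredient_energy import PRINTED_SCHEME, SubstitutionScheme  # noqa: F401
from .stats_inference import RegressionEquation
from .study_io import (DietAssay, DietFormulation, IngredientComposition,
                       load_diet_assays, load_diets, load_ingredients)

__all__ = [
    "data_path",
    "load_ingredient_composition",
    "load_diet_formulations",
    "load_diet_assay_table",
    "printed_ingredient_energy",
    "printed_diet_energy",
    "printed_equations",
    "PRINTED_SCHEME",
]


def data_path(name: str) -> Path:
    return Path(resources.files("broilerne").joinpath("data", name))


def load_ingredient_composition() -> list[IngredientComposition]:
    """All 12 ingredient samples (5+1 wheat, 5+1 wheat bran), DM basis."""
    return load_ingredients(data_path("ingredient_composition.csv"))


def load_diet_formulations(ingredient_ids: list[str] | None = None,
                           ) -> list[DietFormulation]:
    """The reference diet plus one test diet per requested ingredient.

    The packaged file stores the reference formulation and a single test
    template (30% air-dry substitution); the template is instantiated
    for each ingredient id, yielding diets named ``diet_<ingredient>``.
    """
    raw = load_diets(data_path("diet_formulation.csv"))
    by_id = {d.diet_id: d for d in raw}
    ref = by_id["ref"]
    template = by_id["test_template"]
    if ingredient_ids is None:
        ingredient_ids = [i.ingredient_id
                          for i in load_ingredient_composition()]
    diets = [ref]
    for ing in ingredient_ids:
        inclusions = [(ing if name == "TEST_INGREDIENT" else name, pct)
                      for name, pct in template.inclusions]
        ey = {ing if name == "TEST_INGREDIENT" else name
              for name in template.energy_yielding_ids}
        diets.append(DietFormulation(
            diet_id=f"diet_{ing}", role="test", inclusions=inclusions,
            test_ingredient_id=ing, energy_yielding_ids=ey))
    return diets


def load_diet_assay_table() -> list[DietAssay]:
    """Published diet DM / GE / CP, converted to a DM basis on load."""
    return load_diet_assays(data_path("diet_assays.csv"))


def printed_ingredient_energy() -> pd.DataFrame:
    """Published substitution-method ingredient energies and ratios."""
    return pd.read_csv(data_path("ingredient_energy_printed.csv"))


def printed_diet_energy() -> pd.DataFrame:
    """Published diet-level performance and energy table (per-diet means)."""
    return pd.read_csv(data_path("diet_energy_printed.csv"))


def printed_equations() -> dict[str, RegressionEquation]:
    """The published NE prediction equations (MJ/kg DM)."""
    return {
        "wheat": RegressionEquation(
            response="NE", terms=[("ame", 1.968), ("adf", -0.411)],
            intercept=-14.227, r2=0.999, n=5),
        "wheat_bran": RegressionEquation(
            response="NE",
            terms=[("cp", -0.362), ("cf", -0.382), ("adf", -0.244)],
            intercept=20.870, r2=0.785, n=5),
    }
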