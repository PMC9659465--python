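"""Trial data model and delimited-table I/O.

A feeding trial is represented by five tables:

* ``ingredients.csv`` — proximate composition of each feed ingredient
  (DM basis; the ``dm`` column is percent as-fed).
* ``diets.csv`` — long-format diet formulations (air-dry inclusion
  percentages, energy-yielding flags, test-ingredient marker).
* ``diet_assays.csv`` — diet-level dry matter, gross energy and crude
  protein as assayed on the air-dry feed; converted to a DM basis on load.
* ``cage_obs.csv`` — replicate-cage total-collection records (feed intake,
  body weights, excreta mass / gross energy / nitrogen).
* ``chamber_obs.csv`` — respiration-chamber records (feed intake, body
  weights, O2 consumed and CO2 produced, litres).

All energies and compositions are DM basis in memory; air-dry inputs are
converted on load using the record's own ``dm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "IngredientKind",
    "DietRole",
    "IngredientComposition",
    "DietFormulation",
    "DietAssay",
    "CageObservation",
    "ChamberObservation",
    "TrialBundle",
    "SchemaError",
    "TableParseError",
    "RecordValidationError",
    "ReferentialIntegrityError",
    "load_ingredients",
    "load_diets",
    "load_diet_assays",
    "load_cage_observations",
    "load_chamber_observations",
    "load_trial",
    "write_ingredients",
    "write_trial",
    "write_tables",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableParseError(ValueError):
    """A cell could not be parsed as a number."""


class RecordValidationError(ValueError):
    """A record violates a domain invariant."""


class ReferentialIntegrityError(ValueError):
    """A cross-reference (diet_id / ingredient_id) does not resolve."""


class IngredientKind(str, Enum):
    wheat = "wheat"
    wheat_bran = "wheat_bran"
    other = "other"


class DietRole(str, Enum):
    reference = "reference"
    test = "test"


def _check_range(name: str, value: float, lo: float, hi: float,
                 lo_open: bool = False) -> None:
    ok = (lo < value if lo_open else lo <= value) and value <= hi
    if not ok:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


class IngredientComposition(BaseModel):
    """Proximate analysis of one ingredient, DM basis.

    ``dm`` is percent as-fed; ``cp``/``ee``/``cf``/``ndf``/``adf`` are
    percent of DM; ``st`` (starch) is g/kg DM; ``ge`` is MJ/kg DM and may
    be absent (never imputed).
    """

    ingredient_id: str
    kind: IngredientKind = IngredientKind.other
    dm: float
    cp: float
    ee: float
    cf: float
    ndf: float
    adf: float
    st: float
    ge: Optional[float] = None

    @model_validator(mode="after")
    def _invariants(self) -> "IngredientComposition":
        _check_range("dm", self.dm, 0, 100, lo_open=True)
        for name in ("cp", "ee", "cf", "ndf", "adf"):
            _check_range(name, getattr(self, name), 0, 100)
        _check_range("st", self.st, 0, 1000)
        if self.ge is not None:
            _check_range("ge", self.ge, 0, 30, lo_open=True)
        return self


class DietFormulation(BaseModel):
    """One diet's air-dry ingredient inclusions.

    ``inclusions`` preserves formulation order; percentages must total
    100 within 0.05. For test diets, ``substitution_pct`` equals the
    inclusion of ``test_ingredient_id``.
    """

    diet_id: str
    role: DietRole
    inclusions: list[tuple[str, float]]
    test_ingredient_id: Optional[str] = None
    substitution_pct: Optional[float] = None
    energy_yielding_ids: set[str] = set()

    @model_validator(mode="after")
    def _invariants(self) -> "DietFormulation":
        total = sum(p for _, p in self.inclusions)
        if abs(total - 100.0) > 0.05:
            raise ValueError(
                f"diet {self.diet_id}: inclusions sum to {total:.3f}, not 100")
        if self.role is DietRole.test:
            if self.test_ingredient_id is None:
                raise ValueError(f"test diet {self.diet_id} lacks a test ingredient")
            incl = dict(self.inclusions).get(self.test_ingredient_id)
            if incl is None:
                raise ValueError(
                    f"diet {self.diet_id}: test ingredient "
                    f"{self.test_ingredient_id!r} not among inclusions")
            if self.substitution_pct is None:
                self.substitution_pct = incl
            elif abs(self.substitution_pct - incl) > 1e-6:
                raise ValueError(
                    f"diet {self.diet_id}: substitution_pct "
                    f"{self.substitution_pct} != inclusion {incl}")
        return self

    def inclusion_of(self, ingredient_id: str) -> float:
        return dict(self.inclusions).get(ingredient_id, 0.0)


class DietAssay(BaseModel):
    """Diet-level assay, DM basis in memory (``ge`` MJ/kg DM, ``cp`` % DM)."""

    diet_id: str
    dm: float
    ge: float
    cp: float

    @model_validator(mode="after")
    def _invariants(self) -> "DietAssay":
        _check_range("dm", self.dm, 0, 100, lo_open=True)
        _check_range("ge", self.ge, 0, 30, lo_open=True)
        return self


class CageObservation(BaseModel):
    """One replicate cage's 3-d total-collection record.

    Body weights are g per bird; ``feed_intake_dm`` and ``excreta_dm``
    are cage totals in g DM; ``excreta_ge`` MJ/kg DM; ``feed_n`` and
    ``excreta_n`` are g N per kg DM of feed and excreta respectively.
    """

    run_id: str
    diet_id: str
    replicate_id: str
    n_birds: int
    days: int
    bw_initial: float
    bw_final: float
    feed_intake_dm: float
    excreta_dm: float
    excreta_ge: float
    feed_n: float
    excreta_n: float

    @model_validator(mode="after")
    def _invariants(self) -> "CageObservation":
        if self.n_birds < 1 or self.days < 1:
            raise ValueError("n_birds and days must be >= 1")
        if self.bw_final <= 0:
            raise ValueError("bw_final must be positive")
        if self.feed_intake_dm <= 0:
            raise ValueError("feed_intake_dm must be positive")
        if self.excreta_dm < 0:
            raise ValueError("excreta_dm must be non-negative")
        return self


class ChamberObservation(BaseModel):
    """One respiration chamber's 3-d gas-exchange record (litres of gas)."""

    run_id: str
    diet_id: str
    chamber_id: str
    n_birds: int
    days: int
    bw_initial: float
    bw_final: float
    feed_intake_dm: float
    o2_consumed: float
    co2_produced: float

    @model_validator(mode="after")
    def _invariants(self) -> "ChamberObservation":
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if self.o2_consumed <= 0:
            raise ValueError("o2_consumed must be positive")
        if self.co2_produced < 0:
            raise ValueError("co2_produced must be non-negative")
        return self


@dataclass
class TrialBundle:
    """A complete, cross-reference-checked trial."""

    ingredients: list[IngredientComposition]
    diets: list[DietFormulation]
    assays: list[DietAssay]
    cage_obs: list[CageObservation]
    chamber_obs: list[ChamberObservation]

    def diet(self, diet_id: str) -> DietFormulation:
        for d in self.diets:
            if d.diet_id == diet_id:
                return d
        raise KeyError(diet_id)

    def assay(self, diet_id: str) -> DietAssay:
        for a in self.assays:
            if a.diet_id == diet_id:
                return a
        raise KeyError(diet_id)

    def ingredient(self, ingredient_id: str) -> IngredientComposition:
        for i in self.ingredients:
            if i.ingredient_id == ingredient_id:
                return i
        raise KeyError(ingredient_id)


# ---------------------------------------------------------------------------
# readers


def _read_csv(path: Path | str, required: Sequence[str],
              numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableParseError(
                f"{path.name}: non-numeric value {df[col][row]!r} "
                f"in column {col!r}, row {row}")
        df[col] = coerced
    return df


def _build(cls, rows, source: str):
    out = []
    for idx, kwargs in rows:
        try:
            out.append(cls(**kwargs))
        except (pydantic.ValidationError, ValueError) as exc:
            raise RecordValidationError(f"{source}, row {idx}: {exc}") from exc
    return out


_ING_COLS = ["ingredient_id", "kind", "dm", "cp", "ee", "cf", "ndf", "adf", "st"]


def load_ingredients(path: Path | str) -> list[IngredientComposition]:
    """Read ``ingredients.csv``; returns records in row order."""
    df = _read_csv(path, _ING_COLS,
                   ["dm", "cp", "ee", "cf", "ndf", "adf", "st"])
    if "ge" in df.columns:
        df["ge"] = pd.to_numeric(df["ge"], errors="coerce")
    else:
        df["ge"] = float("nan")
    if df.empty:
        logger.warning("%s: empty ingredient table", path)
        return []
    rows = []
    for idx, r in df.iterrows():
        ge = None if pd.isna(r["ge"]) else float(r["ge"])
        rows.append((idx, dict(
            ingredient_id=str(r["ingredient_id"]), kind=r["kind"],
            dm=r["dm"], cp=r["cp"], ee=r["ee"], cf=r["cf"],
            ndf=r["ndf"], adf=r["adf"], st=r["st"], ge=ge)))
    return _build(IngredientComposition, rows, str(path))


def load_diets(path: Path | str) -> list[DietFormulation]:
    """Read long-format ``diets.csv`` and assemble one record per diet."""
    df = _read_csv(path, ["diet_id", "role", "ingredient_id", "inclusion_pct"],
                   ["inclusion_pct"])
    diets = []
    for diet_id, grp in df.groupby("diet_id", sort=False):
        role = DietRole(grp["role"].iloc[0])
        inclusions = list(zip(grp["ingredient_id"].astype(str),
                              grp["inclusion_pct"].astype(float)))
        ey = set()
        if "energy_yielding" in grp.columns:
            ey = set(grp.loc[grp["energy_yielding"].astype(int) == 1,
                             "ingredient_id"].astype(str))
        test_ing = None
        if "is_test_ingredient" in grp.columns:
            marked = grp.loc[grp["is_test_ingredient"].astype(int) == 1,
                             "ingredient_id"]
            if len(marked):
                test_ing = str(marked.iloc[0])
        diets.extend(_build(DietFormulation, [(diet_id, dict(
            diet_id=str(diet_id), role=role, inclusions=inclusions,
            test_ingredient_id=test_ing, energy_yielding_ids=ey))],
            str(path)))
    return diets


def load_diet_assays(path: Path | str, airdry: bool = True) -> list[DietAssay]:
    """Read ``diet_assays.csv``.

    With ``airdry=True`` (the default and the on-disk convention) the GE
    and CP columns are as-assayed on air-dry feed and are divided by
    dm/100 to give DM-basis values.
    """
    df = _read_csv(path, ["diet_id", "dm", "ge", "cp"], ["dm", "ge", "cp"])
    rows = []
    for idx, r in df.iterrows():
        f = r["dm"] / 100.0 if airdry else 1.0
        rows.append((idx, dict(diet_id=str(r["diet_id"]), dm=r["dm"],
                               ge=r["ge"] / f, cp=r["cp"] / f)))
    return _build(DietAssay, rows, str(path))


_CAGE_NUM = ["n_birds", "days", "bw_initial", "bw_final", "feed_intake_dm",
             "excreta_dm", "excreta_ge", "feed_n", "excreta_n"]


def load_cage_observations(path: Path | str) -> list[CageObservation]:
    df = _read_csv(path, ["run_id", "diet_id", "replicate_id"] + _CAGE_NUM,
                   _CAGE_NUM)
    rows = [(idx, dict(run_id=str(r["run_id"]), diet_id=str(r["diet_id"]),
                       replicate_id=str(r["replicate_id"]),
                       n_birds=int(r["n_birds"]), days=int(r["days"]),
                       **{c: float(r[c]) for c in _CAGE_NUM[2:]}))
            for idx, r in df.iterrows()]
    return _build(CageObservation, rows, str(path))


_CHAMBER_NUM = ["n_birds", "days", "bw_initial", "bw_final",
                "feed_intake_dm", "o2_consumed", "co2_produced"]


def load_chamber_observations(path: Path | str) -> list[ChamberObservation]:
    df = _read_csv(path, ["run_id", "diet_id", "chamber_id"] + _CHAMBER_NUM,
                   _CHAMBER_NUM)
    rows = [(idx, dict(run_id=str(r["run_id"]), diet_id=str(r["diet_id"]),
                       chamber_id=str(r["chamber_id"]),
                       n_birds=int(r["n_birds"]), days=int(r["days"]),
                       **{c: float(r[c]) for c in _CHAMBER_NUM[2:]}))
            for idx, r in df.iterrows()]
    return _build(ChamberObservation, rows, str(path))


def _check_integrity(bundle: TrialBundle) -> None:
    diet_ids = {d.diet_id for d in bundle.diets}
    ing_ids = {i.ingredient_id for i in bundle.ingredients}
    for obs in list(bundle.cage_obs) + list(bundle.chamber_obs):
        if obs.diet_id not in diet_ids:
            raise ReferentialIntegrityError(
                f"observation references unknown diet {obs.diet_id!r}")
    for a in bundle.assays:
        if a.diet_id not in diet_ids:
            raise ReferentialIntegrityError(
                f"assay references unknown diet {a.diet_id!r}")
    for d in bundle.diets:
        if d.role is DietRole.test and d.test_ingredient_id not in ing_ids:
            raise ReferentialIntegrityError(
                f"diet {d.diet_id} references unknown ingredient "
                f"{d.test_ingredient_id!r}")


def load_trial(config: Path | str) -> TrialBundle:
    """Load a complete trial from a YAML config naming each table.

    Config keys (paths are resolved relative to the config file)::

        tables:
          ingredients: ingredients.csv
          diets: diets.csv
          diet_assays: diet_assays.csv
          cage_obs: cage_obs.csv
          chamber_obs: chamber_obs.csv

    Raises :class:`ReferentialIntegrityError` if any observation's
    diet_id, or any test diet's ingredient_id, does not resolve.
    """
    config = Path(config)
    cfg = yaml.safe_load(config.read_text())
    tables = cfg["tables"]
    base = config.parent

    def p(key):
        return base / tables[key]

    bundle = TrialBundle(
        ingredients=load_ingredients(p("ingredients")),
        diets=load_diets(p("diets")),
        assays=load_diet_assays(p("diet_assays")),
        cage_obs=load_cage_observations(p("cage_obs")),
        chamber_obs=load_chamber_observations(p("chamber_obs")),
    )
    _check_integrity(bundle)
    return bundle


# ---------------------------------------------------------------------------
# writers


def write_ingredients(ingredients: Sequence[IngredientComposition],
                      path: Path | str) -> None:
    rows = [dict(ingredient_id=i.ingredient_id, kind=i.kind.value, dm=i.dm,
                 cp=i.cp, ee=i.ee, cf=i.cf, ndf=i.ndf, adf=i.adf,
                 st=i.st, ge="" if i.ge is None else i.ge)
            for i in ingredients]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trial(bundle: TrialBundle, outdir: Path | str,
                extra_config: Optional[dict] = None) -> Path:
    """Write all five tables plus a loadable config; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ingredients(bundle.ingredients, outdir / "ingredients.csv")

    diet_rows = []
    for d in bundle.diets:
        for ing, pct in d.inclusions:
            diet_rows.append(dict(
                diet_id=d.diet_id, role=d.role.value, ingredient_id=ing,
                inclusion_pct=pct,
                energy_yielding=int(ing in d.energy_yielding_ids),
                is_test_ingredient=int(ing == d.test_ingredient_id)))
    pd.DataFrame(diet_rows).to_csv(outdir / "diets.csv", index=False)

    # assays are stored air-dry on disk (the assay convention)
    pd.DataFrame([dict(diet_id=a.diet_id, dm=a.dm,
                       ge=a.ge * a.dm / 100.0, cp=a.cp * a.dm / 100.0)
                  for a in bundle.assays]
                 ).to_csv(outdir / "diet_assays.csv", index=False)

    pd.DataFrame([o.model_dump() for o in bundle.cage_obs]
                 ).to_csv(outdir / "cage_obs.csv", index=False)
    pd.DataFrame([o.model_dump() for o in bundle.chamber_obs]
                 ).to_csv(outdir / "chamber_obs.csv", index=False)

    cfg = {"tables": {"ingredients": "ingredients.csv",
                      "diets": "diets.csv",
                      "diet_assays": "diet_assays.csv",
                      "cage_obs": "cage_obs.csv",
                      "chamber_obs": "chamber_obs.csv"}}
    if extra_config:
        cfg.update(extra_config)
    cfg_path = outdir / "trial.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return cfg_path


def write_tables(results: dict[str, pd.DataFrame], path: Path | str) -> list[Path]:
    """Write each named DataFrame as ``<name>.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        target = path / f"{name}.csv"
        df.to_csv(target, index=False)
        written.append(target)
    return written
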