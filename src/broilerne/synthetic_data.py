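"""Synthetic feeding-trial generator with known ground truth.

The generator emulates the balance-trial design the analysis assumes:
per treatment, replicate cages of 8 birds measure metabolizable energy
by 3-day total excreta collection while replicate chambers of 4 birds
measure heat production by open-circuit calorimetry, with test diets
formed by substituting 30% (air-dry) of a reference diet's
energy-yielding fraction with one test ingredient. Runs are replicate
batches: run *r* carries replicate *r* of every diet, so the reference
diet is present in every run and run-wise pairing (chamber -> cage,
test -> reference) is always defined.

Observables are back-solved from the ground truth so that a noise-free
simulation is recovered exactly by the analysis, then perturbed with
multiplicative lognormal noise (mean 1, given CV) — observables are
positive and the published between-replicate dispersions are relative
SDs, which a CV-parameterized lognormal reproduces directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import datasets
from .energy_balance import DEFAULT_CONSTANTS, EnergyConstants
from .ingredient_energy import PRINTED_SCHEME, SubstitutionScheme
from .study_io import (CageObservation, ChamberObservation, DietAssay,
                       DietFormulation, DietRole, IngredientComposition,
                       TrialBundle)

__all__ = [
    "IngredientTruth",
    "TruthSet",
    "GeneratorConfig",
    "DEFAULT_NOISE_CVS",
    "simulate_study",
    "published_truth",
]

#: Between-replicate CVs (percent) of the raw observables, calibrated to
#: the relative SDs the printed diet tables report (heat production ~11%,
#: feed intake ~7%, body weight ~5%, gas-ratio ~3.5%; excreta terms sized
#: so diet AME shows the printed ~2% dispersion).
DEFAULT_NOISE_CVS: dict[str, float] = {
    "fi": 7.4,
    "bw": 5.2,
    "excreta_dm": 5.0,
    "excreta_ge": 2.0,
    "excreta_n": 8.0,
    "thp": 11.2,
    "rq": 3.5,
}


@dataclass(frozen=True)
class IngredientTruth:
    """True energy values of one ingredient, MJ/kg DM."""

    ame: float
    amen: float
    ne: float

    def __post_init__(self) -> None:
        if self.ne > self.ame:
            raise ValueError("ne must not exceed ame")


@dataclass
class TruthSet:
    """Ground truth a simulated study is generated from.

    ``ref_*`` are the reference diet's true energies (MJ/kg DM) and crude
    protein (% DM); test-diet truths are composed by the substitution
    mixing rule E_test = E_ref*a/100 + E_ingredient*b/100. ``diet_ge``
    optionally pins a diet's true gross energy (MJ/kg DM); otherwise GE
    mixes like the other energies. Per-diet true N retention (g/kg DM
    feed) is implied by the AME-AMEn gap.
    """

    ingredients: list[IngredientComposition]
    energy: dict[str, IngredientTruth]
    ref_ge: float
    ref_ame: float
    ref_amen: float
    ref_ne: float
    ref_cp: float
    scheme: SubstitutionScheme = PRINTED_SCHEME
    rq_true: float = 1.0
    diet_ge: dict[str, float] = field(default_factory=dict)
    noise_cvs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_CVS))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.noise_cvs.values()):
            raise ValueError("noise CVs must be non-negative")

    # -- true diet-level quantities -------------------------------------
    def diet_truth(self, ingredient_id: Optional[str]) -> dict[str, float]:
        """True GE/AME/AMEn/NE/CP of the reference (None) or a test diet."""
        if ingredient_id is None:
            return dict(ge=self.ref_ge, ame=self.ref_ame,
                        amen=self.ref_amen, ne=self.ref_ne, cp=self.ref_cp)
        ing = self.energy[ingredient_id]
        a = self.scheme.a_pct / 100.0
        b = self.scheme.b_pct / 100.0
        comp = {i.ingredient_id: i for i in self.ingredients}[ingredient_id]
        ing_ge = comp.ge if comp.ge is not None else self.ref_ge
        ge = self.diet_ge.get(f"diet_{ingredient_id}",
                              self.ref_ge * a + ing_ge * b)
        return dict(ge=ge,
                    ame=self.ref_ame * a + ing.ame * b,
                    amen=self.ref_amen * a + ing.amen * b,
                    ne=self.ref_ne * a + ing.ne * b,
                    cp=self.ref_cp * a + comp.cp * b)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "ingredients": [i.model_dump() for i in self.ingredients],
            "energy": {k: asdict(v) for k, v in self.energy.items()},
            "ref_ge": self.ref_ge, "ref_ame": self.ref_ame,
            "ref_amen": self.ref_amen, "ref_ne": self.ref_ne,
            "ref_cp": self.ref_cp,
            "scheme": asdict(self.scheme), "rq_true": self.rq_true,
            "diet_ge": self.diet_ge, "noise_cvs": self.noise_cvs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Path | str) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            ingredients=[IngredientComposition(**i) for i in d["ingredients"]],
            energy={k: IngredientTruth(**v) for k, v in d["energy"].items()},
            ref_ge=d["ref_ge"], ref_ame=d["ref_ame"],
            ref_amen=d["ref_amen"], ref_ne=d["ref_ne"], ref_cp=d["ref_cp"],
            scheme=SubstitutionScheme(**d["scheme"]),
            rq_true=d["rq_true"], diet_ge=d["diet_ge"],
            noise_cvs=d["noise_cvs"], seed=d["seed"])


@dataclass(frozen=True)
class GeneratorConfig:
    """Trial dimensions; defaults mirror the emulated design
    (6 runs, 2 diets at a time, 6 replicates, cages of 8 and chambers of
    4 birds, 3-day balance window)."""

    n_runs: int = 6
    diets_per_run: int = 2
    n_reference_diets: int = 2
    cage_replicates: int = 6
    chamber_replicates: int = 6
    birds_per_cage: int = 8
    birds_per_chamber: int = 4
    days: int = 3
    bw_start_mean: float = 356.0   # g at the start of the balance window
    bw_start_sd: float = 18.0
    fi_mean: float = 56.0          # g DM per bird per day
    fcr: float = 1.5               # g feed DM per g gain
    excreta_ge_mean: float = 14.0  # MJ/kg excreta DM

    def __post_init__(self) -> None:
        for name in ("n_runs", "diets_per_run", "cage_replicates",
                     "chamber_replicates", "birds_per_cage",
                     "birds_per_chamber", "days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _lognorm_factor(rng: np.random.Generator, cv_pct: float,
                    size=None) -> np.ndarray | float:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv_pct == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p((cv_pct / 100.0) ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _diet_list(truth: TruthSet, n_ref: int) -> list[tuple[str, Optional[str]]]:
    diets: list[tuple[str, Optional[str]]] = [
        (f"ref_{i + 1}" if n_ref > 1 else "ref", None) for i in range(n_ref)]
    diets += [(f"diet_{ing}", ing) for ing in truth.energy]
    return diets


def simulate_study(truth: TruthSet, config: GeneratorConfig = GeneratorConfig(),
                   seed: Optional[int] = None,
                   constants: EnergyConstants = DEFAULT_CONSTANTS,
                   ) -> tuple[TrialBundle, TruthSet]:
    """Generate a complete trial bundle from ground truth.

    Returns the bundle and the truth echo. Deterministic for a fixed
    seed (``truth.seed`` unless overridden): each run draws from its own
    spawned substream, so re-simulating run *r* alone reproduces it.
    """
    seed = truth.seed if seed is None else seed
    run_streams = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(seed).spawn(config.n_runs)]
    cvs = truth.noise_cvs
    diets = _diet_list(truth, config.n_reference_diets)

    formulations: list[DietFormulation] = []
    assays: list[DietAssay] = []
    template = {d.diet_id: d
                for d in datasets.load_diet_formulations(
                    list(truth.energy))}
    for diet_id, ing in diets:
        dt = truth.diet_truth(ing)
        if ing is None:
            formulations.append(
                template["ref"].model_copy(update={"diet_id": diet_id}))
        else:
            formulations.append(template[diet_id])
        assays.append(DietAssay(diet_id=diet_id, dm=93.5, ge=dt["ge"],
                                cp=dt["cp"]))

    cages: list[CageObservation] = []
    chambers: list[ChamberObservation] = []

    def grow(rng, n_birds: int) -> tuple[float, float, float]:
        """(bw_initial, bw_final, fi_per_bird_day) with linear gain."""
        fi = config.fi_mean * _lognorm_factor(rng, cvs.get("fi", 0.0))
        bw0 = config.bw_start_mean * _lognorm_factor(rng, cvs.get("bw", 0.0))
        bw1 = bw0 + (fi / config.fcr) * config.days
        return bw0, bw1, fi

    for diet_id, ing in diets:
        dt = truth.diet_truth(ing)
        feed_n = dt["cp"] * 10.0 / constants.protein_per_n  # g N/kg DM
        tnr_kg = (dt["ame"] - dt["amen"]) * 1000.0 / constants.n_correction
        for rep in range(config.cage_replicates):
            run = rep % config.n_runs
            rng = run_streams[run]
            bw0, bw1, fi = grow(rng, config.birds_per_cage)
            fi_total = fi * config.days * config.birds_per_cage
            exc_energy = (dt["ge"] - dt["ame"]) * fi_total / 1000.0  # MJ
            m_true = exc_energy * 1000.0 / config.excreta_ge_mean    # g DM
            exc_n_per_kg = (feed_n - tnr_kg) * fi_total / m_true
            cages.append(CageObservation(
                run_id=f"run{run + 1}", diet_id=diet_id,
                replicate_id=f"cage{rep + 1}",
                n_birds=config.birds_per_cage, days=config.days,
                bw_initial=bw0, bw_final=bw1, feed_intake_dm=fi_total,
                excreta_dm=m_true * _lognorm_factor(
                    rng, cvs.get("excreta_dm", 0.0)),
                excreta_ge=config.excreta_ge_mean * _lognorm_factor(
                    rng, cvs.get("excreta_ge", 0.0)),
                feed_n=feed_n,
                excreta_n=exc_n_per_kg * _lognorm_factor(
                    rng, cvs.get("excreta_n", 0.0))))
        for rep in range(config.chamber_replicates):
            run = rep % config.n_runs
            rng = run_streams[run]
            bw0, bw1, fi = grow(rng, config.birds_per_chamber)
            abw = (bw0 + bw1) / 2.0
            mbw = (abw / 1000.0) ** constants.mbw_exponent
            fi_kg = fi / 1000.0
            fhp = constants.fhp_coef / 1000.0
            thp_per_mbw = fi_kg * (dt["ame"] - dt["ne"]) / mbw + fhp
            thp_kj = (thp_per_mbw * mbw * 1000.0 *
                      config.birds_per_chamber * config.days *
                      _lognorm_factor(rng, cvs.get("thp", 0.0)))
            rq = truth.rq_true * _lognorm_factor(rng, cvs.get("rq", 0.0))
            o2 = thp_kj / (constants.thp_o2 + constants.thp_co2 * rq)
            chambers.append(ChamberObservation(
                run_id=f"run{run + 1}", diet_id=diet_id,
                chamber_id=f"chamber{rep + 1}",
                n_birds=config.birds_per_chamber, days=config.days,
                bw_initial=bw0, bw_final=bw1, feed_intake_dm=fi * config.days
                * config.birds_per_chamber,
                o2_consumed=o2, co2_produced=rq * o2))

    bundle = TrialBundle(ingredients=list(truth.ingredients),
                         diets=formulations, assays=assays,
                         cage_obs=cages, chamber_obs=chambers)
    return bundle, truth


def published_truth(seed: int = 0) -> TruthSet:
    """Ground truth transcribed from the published study tables.

    Ingredient energies are the published substitution-method values of
    the 5 wheat and 5 wheat-bran samples; the reference diet carries its
    published AME/AMEn/NE; per-diet true GE comes from the published diet
    assays (DM basis); ingredient GE is back-computed from AME and the
    published AME/GE ratio.
    """
    printed = datasets.printed_ingredient_energy().set_index("ingredient_id")
    comps = []
    energy: dict[str, IngredientTruth] = {}
    for comp in datasets.load_ingredient_composition():
        iid = comp.ingredient_id
        if iid.endswith("_v"):   # validation samples are held out of truth
            continue
        row = printed.loc[iid]
        comp = comp.model_copy(
            update={"ge": float(row["ame"] / (row["ame_ge"] / 100.0))})
        comps.append(comp)
        energy[iid] = IngredientTruth(ame=float(row["ame"]),
                                      amen=float(row["amen"]),
                                      ne=float(row["ne"]))
    assays = {a.diet_id: a for a in datasets.load_diet_assay_table()}
    ref = assays["ref"]
    diet_ge = {d: a.ge for d, a in assays.items() if d.startswith("diet_")}
    return TruthSet(ingredients=comps, energy=energy,
                    ref_ge=ref.ge, ref_ame=13.29, ref_amen=13.06,
                    ref_ne=8.20, ref_cp=ref.cp,
                    scheme=PRINTED_SCHEME, rq_true=1.00,
                    diet_ge=diet_ge, seed=seed)
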