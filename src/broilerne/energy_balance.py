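"""Per-diet energy bookkeeping for broiler balance trials.

The energy cascade implemented here follows the classical indirect
calorimetry partition:

* **AME** (apparent metabolizable energy, MJ/kg DM) — gross energy of the
  feed minus gross energy of the excreta, per kg feed DM, measured by
  total excreta collection.
* **AMEn** — AME corrected to zero nitrogen retention by charging 34.39 kJ
  per g of retained N against the feed.
* **THP** (total heat production) — Brouwer-form thermal equivalents of the
  respiratory gas exchange, 16.1753 kJ/L O2 + 5.0208 kJ/L CO2.
* **FHP** (fasting heat production) — allometric maintenance heat,
  450 kJ per kg^0.70 of body mass per day.
* **HI** = THP − FHP, **NEI** = AMEI − HI, **RE** = AMEI − THP, and RE is
  partitioned into protein retention (from the N balance at 6.25 g
  protein/g N and 23.85 kJ/g protein) and fat retention (remainder).

All flow quantities are expressed per kg of metabolic body weight
(BW^0.70, in kg) per day, so FHP is the constant 0.450 MJ/kg^0.70/d and
HI = THP − 0.450 in the reported unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

from .study_io import CageObservation, ChamberObservation, DietAssay

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyConstants",
    "PerformanceSummary",
    "DietEnergy",
    "EnergyBalance",
    "metabolic_weight",
    "performance",
    "thp_from_gas",
    "respiratory_quotient",
    "diet_ame",
    "energy_balance",
    "diet_net_energy",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Thermal and nutritional constants of the energy partition.

    thp_o2, thp_co2
        kJ per litre of O2 consumed / CO2 produced (Brouwer-form
        coefficients, methane and urinary-N terms omitted for poultry).
    fhp_coef
        Fasting heat production, kJ per kg^0.70 per day.
    mbw_exponent
        Allometric exponent of metabolic body weight.
    n_correction
        kJ charged per g of retained N in the zero-retention correction
        (34.39 MJ/kg N).
    protein_per_n, protein_energy
        g protein per g N (6.25) and kJ per g body protein
        (5.7 kcal/g x 4.184 = 23.85 kJ/g).
    """

    thp_o2: float = 16.1753
    thp_co2: float = 5.0208
    fhp_coef: float = 450.0
    mbw_exponent: float = 0.70
    n_correction: float = 34.39
    protein_per_n: float = 6.25
    protein_energy: float = 23.85

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"EnergyConstants.{name} must be positive")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


DEFAULT_CONSTANTS = EnergyConstants()


@dataclass
class PerformanceSummary:
    """Growth performance of one replicate (per-bird basis)."""

    abw: float            # average body weight, g
    adg: float            # average daily gain, g/bird/d
    fi: float             # feed intake, g DM/bird/d
    fcr: Optional[float]  # g DM feed per g gain; absent if gain <= 0
    mbw: float            # metabolic body weight, kg^0.70


@dataclass
class DietEnergy:
    """Diet-level energy values, MJ/kg DM, with utilization ratios (%)."""

    ge: Optional[float] = None
    ame: Optional[float] = None
    amen: Optional[float] = None
    ne: Optional[float] = None
    ame_ge: Optional[float] = None
    amen_ge: Optional[float] = None
    ne_ame: Optional[float] = None
    ne_amen: Optional[float] = None


@dataclass
class EnergyBalance:
    """Daily energy flows of one chamber, MJ per kg^0.70 per day."""

    amei: float
    thp: float
    fhp: float
    hi: float
    nei: float
    re: float
    rq: float
    re_protein: Optional[float] = None
    re_fat: Optional[float] = None
    tnr: Optional[float] = None  # g N retained per bird per day
    flags: tuple[str, ...] = ()


def metabolic_weight(abw: float,
                     constants: EnergyConstants = DEFAULT_CONSTANTS) -> float:
    """Metabolic body weight (kg^0.70) of a bird of ``abw`` grams."""
    if not abw > 0:
        raise ValueError(f"abw must be positive, got {abw}")
    return (abw / 1000.0) ** constants.mbw_exponent


def performance(obs: Union[CageObservation, ChamberObservation],
                constants: EnergyConstants = DEFAULT_CONSTANTS,
                ) -> PerformanceSummary:
    """Per-bird performance metrics of one cage or chamber record.

    ABW is the mean of initial and final weight; ADG the per-bird gain
    over the balance period; FI the per-bird daily DM intake. FCR is
    reported absent (with a warning) when there was no positive gain.
    """
    abw = (obs.bw_initial + obs.bw_final) / 2.0
    adg = (obs.bw_final - obs.bw_initial) / obs.days
    fi = obs.feed_intake_dm / (obs.days * obs.n_birds)
    if adg > 0:
        fcr = fi / adg
    else:
        fcr = None
        logger.warning("%s/%s: non-positive gain, FCR not defined",
                       obs.run_id, obs.diet_id)
    return PerformanceSummary(abw=abw, adg=adg, fi=fi, fcr=fcr,
                              mbw=metabolic_weight(abw, constants))


def thp_from_gas(o2: float, co2: float,
                 constants: EnergyConstants = DEFAULT_CONSTANTS) -> float:
    """Total heat production (kJ) from litres of O2 consumed and CO2 produced."""
    if o2 < 0 or co2 < 0:
        raise ValueError("gas volumes must be non-negative")
    return constants.thp_o2 * o2 + constants.thp_co2 * co2


def respiratory_quotient(o2: float, co2: float) -> float:
    """RQ = litres CO2 expired per litre O2 consumed."""
    if not o2 > 0:
        raise ValueError("o2 must be positive")
    return co2 / o2


def diet_ame(obs: CageObservation, assay: DietAssay,
             constants: EnergyConstants = DEFAULT_CONSTANTS,
             ) -> tuple[float, float, float]:
    """AME and AMEn of a diet from one total-collection record.

    Returns ``(ame, amen, tnr)`` where ame/amen are MJ/kg DM and tnr is
    g N retained per bird per day. The N correction is applied per kg of
    DM feed: amen = ame − 34.39 kJ/g × (g N retained per kg feed)/1000.
    """
    fi = obs.feed_intake_dm  # g DM, cage total
    ame = (assay.ge * fi - obs.excreta_ge * obs.excreta_dm) / fi
    if ame < 0:
        logger.warning("%s/%s: excreta energy exceeds intake energy "
                       "(ame=%.3f)", obs.run_id, obs.diet_id, ame)
    tnr_per_kg_feed = obs.feed_n - obs.excreta_n * (obs.excreta_dm / fi)
    amen = ame - constants.n_correction * tnr_per_kg_feed / 1000.0
    tnr = tnr_per_kg_feed * (fi / 1000.0) / (obs.days * obs.n_birds)
    return ame, amen, tnr


def energy_balance(chamber: ChamberObservation,
                   ame: float,
                   tnr_per_kg_feed: Optional[float] = None,
                   constants: EnergyConstants = DEFAULT_CONSTANTS,
                   ) -> EnergyBalance:
    """Full energy partition of one chamber record.

    ``ame`` (MJ/kg DM) and, when available, ``tnr_per_kg_feed`` (g N
    retained per kg DM feed) come from the paired total-collection
    replicate of the same run and diet, because chamber birds undergo no
    excreta collection. All flows are MJ per kg^0.70 per day.
    """
    perf = performance(chamber, constants)
    fi_kg = perf.fi / 1000.0
    amei = ame * fi_kg / perf.mbw
    thp_kj_total = thp_from_gas(chamber.o2_consumed, chamber.co2_produced,
                                constants)
    thp = thp_kj_total / 1000.0 / (chamber.n_birds * chamber.days) / perf.mbw
    fhp = constants.fhp_coef / 1000.0  # MJ per kg^0.70 per day, by definition
    hi = thp - fhp
    nei = amei - hi
    re = amei - thp
    rq = respiratory_quotient(chamber.o2_consumed, chamber.co2_produced)

    flags: list[str] = []
    if hi < 0:
        flags.append("negative_hi")
        logger.warning("%s/%s: HI=%.3f < 0 (possible FHP overestimate)",
                       chamber.run_id, chamber.chamber_id, hi)
    if re < 0:
        flags.append("negative_re")

    re_protein = re_fat = tnr = None
    if tnr_per_kg_feed is not None:
        tnr = tnr_per_kg_feed * fi_kg  # g N/bird/d
        re_protein = (tnr * constants.protein_per_n *
                      constants.protein_energy / 1000.0) / perf.mbw
        re_fat = re - re_protein
    return EnergyBalance(amei=amei, thp=thp, fhp=fhp, hi=hi, nei=nei,
                         re=re, rq=rq, re_protein=re_protein,
                         re_fat=re_fat, tnr=tnr, flags=tuple(flags))


def diet_net_energy(ame: float, amei: float, nei: float,
                    amen: Optional[float] = None,
                    ge: Optional[float] = None) -> DietEnergy:
    """Diet NE (MJ/kg DM) from the intake-scale NEI/AMEI ratio.

    NE = AME x (NEI / AMEI): the diet's metabolizable energy discounted
    by the measured heat-increment share of intake. Ratios (%) are
    populated for whichever of ``amen`` and ``ge`` are supplied.
    """
    if not amei > 0:
        raise ValueError("amei must be positive")
    ne = ame * nei / amei
    de = DietEnergy(ge=ge, ame=ame, amen=amen, ne=ne)
    de.ne_ame = 100.0 * ne / ame if ame else None
    if amen:
        de.ne_amen = 100.0 * ne / amen
    if ge:
        de.ame_ge = 100.0 * ame / ge
        if amen:
            de.amen_ge = 100.0 * amen / ge
    return de
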