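"""Model/Results surface of the package.

:class:`NetEnergyStudy` is built from a trial bundle (real tables or a
synthetic study); its :meth:`~NetEnergyStudy.fit` runs the complete
analysis — per-replicate energy balances, run-wise diet energies,
substitution-method ingredient values, ANOVA across diets, correlation
screening and stepwise NE prediction equations — and returns a
:class:`NetEnergyStudyResults` carrying the derived tables, fitted
equations and diagnostics, with a :meth:`~NetEnergyStudyResults.summary`
text table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import study_io
from .energy_balance import (DEFAULT_CONSTANTS, EnergyConstants, diet_ame,
                             diet_net_energy, energy_balance, performance)
from .ingredient_energy import (PRINTED_SCHEME, IngredientEnergyValues,
                                SubstitutionScheme, ingredient_energy,
                                substitution_levels, summarize_samples)
from .stats_inference import (AnovaResult, CorrelationMatrix,
                              RegressionEquation, ValidationResult,
                              one_way_anova, pearson_matrix, stepwise_fit,
                              validate)
from .study_io import DietRole, TrialBundle

logger = logging.getLogger(__name__)

__all__ = ["NetEnergyStudy", "NetEnergyStudyResults",
           "published_panel", "fit_published_equation"]

_CANDIDATES = ["ame", "amen", "cp", "ee", "cf", "ndf", "adf", "st"]


class NetEnergyStudy:
    """Net-energy determination model for one feeding trial.

    Parameters
    ----------
    bundle
        The trial's ingredients, diets, assays and observations.
    constants
        Thermal/nutritional constants of the energy partition.
    scheme
        Substitution shares (a%, b%) used to invert diet energies to
        ingredient energies. Default: the printed study constants
        (67.58, 31.32). Pass ``scheme="recompute"`` to derive them from
        the formulations and ingredient DM values.
    """

    def __init__(self, bundle: TrialBundle,
                 constants: EnergyConstants = DEFAULT_CONSTANTS,
                 scheme: SubstitutionScheme | str = PRINTED_SCHEME):
        self.bundle = bundle
        self.constants = constants
        self.scheme = scheme

    @classmethod
    def from_config(cls, path: Path | str) -> "NetEnergyStudy":
        """Build from a YAML trial config (see :func:`study_io.load_trial`).

        Optional ``constants:`` overrides and ``use_printed_ab: false``
        (to recompute substitution shares) are honoured.
        """
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        bundle = study_io.load_trial(path)
        constants = EnergyConstants(**cfg.get("constants", {}))
        scheme: SubstitutionScheme | str = PRINTED_SCHEME
        if not cfg.get("use_printed_ab", True):
            scheme = "recompute"
        elif "scheme" in cfg:
            scheme = SubstitutionScheme(**cfg["scheme"])
        return cls(bundle, constants=constants, scheme=scheme)

    @classmethod
    def from_synthetic(cls, truth=None, config=None, seed: Optional[int] = None,
                       constants: EnergyConstants = DEFAULT_CONSTANTS,
                       ) -> "NetEnergyStudy":
        """Simulate a study (default: published ground truth) and wrap it."""
        from .synthetic_data import GeneratorConfig, published_truth, simulate_study
        truth = truth if truth is not None else published_truth()
        config = config if config is not None else GeneratorConfig()
        bundle, _ = simulate_study(truth, config, seed=seed,
                                   constants=constants)
        model = cls(bundle, constants=constants, scheme=truth.scheme)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    def _resolve_scheme(self, test_diet) -> SubstitutionScheme:
        if isinstance(self.scheme, SubstitutionScheme):
            return self.scheme
        ref = next(d for d in self.bundle.diets
                   if d.role is DietRole.reference)
        return substitution_levels(ref, test_diet, self.bundle.ingredients)

    def fit(self, alpha: float = 0.05, alpha_enter: float = 0.05,
            alpha_remove: float = 0.10, collinearity_alpha: float = 0.05,
            fit_equations: bool = True,
            anova: bool = True) -> "NetEnergyStudyResults":
        """Run the full analysis and return the results object."""
        bundle, constants = self.bundle, self.constants
        assay = {a.diet_id: a for a in bundle.assays}

        # --- stage 1: total-collection records -> AME/AMEn/TNR ---------
        cage_rows = []
        for obs in bundle.cage_obs:
            perf = performance(obs, constants)
            ame, amen, tnr = diet_ame(obs, assay[obs.diet_id], constants)
            tnr_kg = (ame - amen) * 1000.0 / constants.n_correction
            cage_rows.append(dict(
                run_id=obs.run_id, diet_id=obs.diet_id,
                replicate_id=obs.replicate_id, abw=perf.abw, adg=perf.adg,
                fi=perf.fi, fcr=perf.fcr, mbw=perf.mbw,
                ame=ame, amen=amen, tnr=tnr, tnr_per_kg_feed=tnr_kg))
        cage_table = pd.DataFrame(cage_rows)
        if cage_table.empty:
            raise ValueError("no cage observations in bundle")
        run_diet = cage_table.groupby(["run_id", "diet_id"])[
            ["ame", "amen", "tnr_per_kg_feed"]].mean()

        def paired(run_id: str, diet_id: str) -> pd.Series:
            try:
                return run_diet.loc[(run_id, diet_id)]
            except KeyError:
                logger.warning("no paired cage for %s/%s; using diet mean",
                               run_id, diet_id)
                return cage_table[cage_table.diet_id == diet_id][
                    ["ame", "amen", "tnr_per_kg_feed"]].mean()

        # --- stage 2: chamber records -> energy balance -----------------
        chamber_rows = []
        for obs in bundle.chamber_obs:
            pair = paired(obs.run_id, obs.diet_id)
            bal = energy_balance(obs, float(pair["ame"]),
                                 float(pair["tnr_per_kg_feed"]), constants)
            perf = performance(obs, constants)
            chamber_rows.append(dict(
                run_id=obs.run_id, diet_id=obs.diet_id,
                chamber_id=obs.chamber_id, abw=perf.abw, fi=perf.fi,
                amei=bal.amei, thp=bal.thp, fhp=bal.fhp, hi=bal.hi,
                nei=bal.nei, re=bal.re, re_protein=bal.re_protein,
                re_fat=bal.re_fat, rq=bal.rq, tnr=bal.tnr,
                flags=";".join(bal.flags)))
        chamber_table = pd.DataFrame(chamber_rows)

        # --- stage 3: run-wise diet energies ----------------------------
        diet_run_rows = []
        if not chamber_table.empty:
            grouped = chamber_table.groupby(["run_id", "diet_id"])[
                ["amei", "nei"]].mean()
            for (run_id, diet_id), flows in grouped.iterrows():
                pair = paired(run_id, diet_id)
                de = diet_net_energy(float(pair["ame"]),
                                     float(flows["amei"]),
                                     float(flows["nei"]),
                                     amen=float(pair["amen"]),
                                     ge=assay[diet_id].ge)
                diet_run_rows.append(dict(
                    run_id=run_id, diet_id=diet_id, ge=de.ge, ame=de.ame,
                    amen=de.amen, ne=de.ne, amei=flows["amei"],
                    nei=flows["nei"], ame_ge=de.ame_ge, amen_ge=de.amen_ge,
                    ne_ame=de.ne_ame, ne_amen=de.ne_amen))
        diet_run_table = pd.DataFrame(diet_run_rows)
        diet_energy_table = (
            diet_run_table.drop(columns="run_id")
            .groupby("diet_id", sort=False).mean().reset_index()
            if not diet_run_table.empty else pd.DataFrame())

        # --- stage 4: substitution-method ingredient energies -----------
        ref_diets = [d.diet_id for d in bundle.diets
                     if d.role is DietRole.reference]
        ingredient_records: list[IngredientEnergyValues] = []
        ingredient_run_values: dict[str, dict[str, list[float]]] = {}
        if not diet_run_table.empty:
            by_run = dict(tuple(diet_run_table.groupby("run_id")))
            for diet in bundle.diets:
                if diet.role is not DietRole.test:
                    continue
                scheme = self._resolve_scheme(diet)
                comp = bundle.ingredient(diet.test_ingredient_id)
                per_run = {"ame": [], "amen": [], "ne": []}
                for run_id, rt in by_run.items():
                    trow = rt[rt.diet_id == diet.diet_id]
                    rrow = rt[rt.diet_id.isin(ref_diets)]
                    if trow.empty or rrow.empty:
                        continue
                    vals = ingredient_energy(
                        float(trow["ame"].iloc[0]),
                        float(trow["amen"].iloc[0]),
                        float(trow["ne"].iloc[0]),
                        float(rrow["ame"].mean()),
                        float(rrow["amen"].mean()),
                        float(rrow["ne"].mean()),
                        scheme, ingredient_id=diet.test_ingredient_id,
                        ge=comp.ge)
                    for key in per_run:
                        per_run[key].append(getattr(vals, key))
                if not per_run["ame"]:
                    continue
                ame_m = float(np.mean(per_run["ame"]))
                amen_m = float(np.mean(per_run["amen"]))
                ne_m = float(np.mean(per_run["ne"]))
                mean_vals = IngredientEnergyValues(
                    ingredient_id=comp.ingredient_id,
                    ame=ame_m, amen=amen_m, ne=ne_m,
                    ame_ge=100.0 * ame_m / comp.ge if comp.ge else None,
                    amen_ge=100.0 * amen_m / comp.ge if comp.ge else None)
                ingredient_records.append(mean_vals)
                ingredient_run_values[comp.ingredient_id] = per_run

        kind_of = {i.ingredient_id: i.kind.value
                   for i in bundle.ingredients}
        ingredient_table = pd.DataFrame([
            dict(ingredient_id=v.ingredient_id,
                 kind=kind_of.get(v.ingredient_id, "other"),
                 ame=v.ame, amen=v.amen, ne=v.ne, ame_ge=v.ame_ge,
                 amen_ge=v.amen_ge, ne_ame=v.ne_ame, ne_amen=v.ne_amen)
            for v in ingredient_records])

        # --- stage 5: ANOVA across diets --------------------------------
        anova_results: dict[str, AnovaResult] = {}
        for var, table in (("ame", cage_table), ("fi", cage_table),
                           ("thp", chamber_table), ("nei", chamber_table),
                           ("re", chamber_table)):
            if not anova or table.empty or var not in table:
                continue
            groups = {d: g[var].dropna().to_numpy()
                      for d, g in table.groupby("diet_id", sort=False)}
            groups = {d: v for d, v in groups.items() if v.size >= 2}
            if len(groups) >= 2:
                try:
                    anova_results[var] = one_way_anova(groups, alpha=alpha)
                except ValueError:
                    pass

        # --- stage 6: correlations and prediction equations -------------
        correlations: dict[str, CorrelationMatrix] = {}
        equations: dict[str, RegressionEquation] = {}
        panels: dict[str, pd.DataFrame] = {}
        if fit_equations and not ingredient_table.empty:
            comp_by_id = {i.ingredient_id: i for i in bundle.ingredients}
            for kind, sub in ingredient_table.groupby("kind"):
                rows = []
                for _, r in sub.iterrows():
                    c = comp_by_id[r["ingredient_id"]]
                    rows.append(dict(
                        ingredient_id=r["ingredient_id"],
                        cp=c.cp, ee=c.ee, cf=c.cf, ndf=c.ndf, adf=c.adf,
                        st=c.st, ge=c.ge, ame=r["ame"], amen=r["amen"],
                        ne=r["ne"]))
                panel = pd.DataFrame(rows)
                panels[kind] = panel
                if len(panel) >= 4:
                    correlations[kind] = pearson_matrix(
                        panel.drop(columns="ingredient_id"))
                    equations[kind] = stepwise_fit(
                        panel["ne"], panel[_CANDIDATES], response="NE",
                        alpha_enter=alpha_enter, alpha_remove=alpha_remove,
                        collinearity_alpha=collinearity_alpha)

        return NetEnergyStudyResults(
            model=self, constants=constants,
            cage_table=cage_table, chamber_table=chamber_table,
            diet_run_table=diet_run_table,
            diet_energy=diet_energy_table,
            ingredient_values=ingredient_table,
            ingredient_records=ingredient_records,
            ingredient_run_values=ingredient_run_values,
            anova=anova_results, correlations=correlations,
            equations=equations,
            panels=panels)


@dataclass
class NetEnergyStudyResults:
    """Fitted results of a :class:`NetEnergyStudy`."""

    model: NetEnergyStudy
    constants: EnergyConstants
    cage_table: pd.DataFrame
    chamber_table: pd.DataFrame
    diet_run_table: pd.DataFrame
    diet_energy: pd.DataFrame
    ingredient_values: pd.DataFrame
    ingredient_records: list[IngredientEnergyValues]
    ingredient_run_values: dict[str, dict[str, list[float]]]
    anova: dict[str, AnovaResult]
    correlations: dict[str, CorrelationMatrix]
    equations: dict[str, RegressionEquation]
    panels: dict[str, pd.DataFrame] = field(default_factory=dict)

    def ingredient_summary(self, kind: str, variable: str = "ne"):
        """Cross-sample mean/SD/CV/SEM of one energy variable of a kind."""
        sub = self.ingredient_values[self.ingredient_values.kind == kind]
        reps = [self.ingredient_run_values[i][variable]
                for i in sub.ingredient_id
                if i in self.ingredient_run_values
                and len(self.ingredient_run_values[i][variable]) >= 2]
        return summarize_samples(sub[variable].to_numpy(),
                                 replicates=reps if reps else None)

    def validate_equation(self, kind: str,
                          holdout: Sequence[tuple[Mapping[str, float], float]],
                          pooled: bool = True) -> ValidationResult:
        """Predicted-vs-measured check of a fitted equation on new samples."""
        eq = self.equations[kind]
        training = None
        if pooled and kind in self.panels:
            training = [(row.to_dict(), row["ne"])
                        for _, row in self.panels[kind].iterrows()]
        return validate(eq, holdout, training=training)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"cage_results": self.cage_table,
               "energy_balance": self.chamber_table,
               "diet_energy": self.diet_energy,
               "ingredient_energy": self.ingredient_values}
        if self.equations:
            rows = []
            for kind, eq in self.equations.items():
                row = dict(kind=kind, response=eq.response,
                           intercept=eq.intercept, r2=eq.r2, n=eq.n)
                row.update({name: coef for name, coef in eq.terms})
                rows.append(row)
            out["equations"] = pd.DataFrame(rows)
        for kind, cm in self.correlations.items():
            out[f"correlation_{kind}"] = cm.r.reset_index(
                names="variable")
        return out

    def to_csv(self, outdir: Path | str) -> list[Path]:
        return study_io.write_tables(self.tables(), outdir)

    def summary(self) -> str:
        lines = ["Net-energy study results",
                 "=" * 24, ""]
        if not self.diet_energy.empty:
            lines.append("Diet energies (MJ/kg DM):")
            lines.append(self.diet_energy[
                ["diet_id", "ame", "amen", "ne"]].round(2).to_string(
                    index=False))
            lines.append("")
        if not self.ingredient_values.empty:
            lines.append("Ingredient energies (MJ/kg DM, substitution method):")
            lines.append(self.ingredient_values[
                ["ingredient_id", "ame", "amen", "ne", "ne_ame"]
            ].round(2).to_string(index=False))
            lines.append("")
            for kind in sorted(self.ingredient_values.kind.unique()):
                s = self.ingredient_summary(kind, "ne")
                cv = f", CV {s.cv_pct:.1f}%" if s.cv_pct is not None else ""
                lines.append(f"  mean {kind} NE = {s.mean:.2f} MJ/kg DM "
                             f"(n={s.n}{cv})")
            lines.append("")
        for kind, eq in self.equations.items():
            lines.append(f"Prediction equation ({kind}): {eq}")
        if self.anova:
            lines.append("")
            lines.append("ANOVA across diets (p-values): " + ", ".join(
                f"{var}={res.p_value:.3f}" for var, res in self.anova.items()))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# published sample panels (no raw replicate records exist for them)


def published_panel(kind: str) -> pd.DataFrame:
    """Sample-level panel of the published Experiment-2 ingredient values.

    Combines each sample's proximate composition with its published
    substitution-method AME/AMEn/NE; validation samples (``*_v``) are
    excluded. ``kind`` is ``"wheat"`` or ``"wheat_bran"``.
    """
    from . import datasets
    printed = datasets.printed_ingredient_energy()
    comps = {c.ingredient_id: c for c in datasets.load_ingredient_composition()}
    rows = []
    for _, r in printed.iterrows():
        if r["kind"] != kind or r["ingredient_id"].endswith("_v"):
            continue
        c = comps[r["ingredient_id"]]
        rows.append(dict(ingredient_id=r["ingredient_id"], cp=c.cp, ee=c.ee,
                         cf=c.cf, ndf=c.ndf, adf=c.adf, st=c.st,
                         ame=r["ame"], amen=r["amen"], ne=r["ne"]))
    return pd.DataFrame(rows)


def fit_published_equation(kind: str = "wheat", stepwise: bool = True,
                           alpha_enter: float = 0.05,
                           alpha_remove: float = 0.10,
                           collinearity_alpha: float = 0.05,
                           ) -> RegressionEquation:
    """Refit the NE prediction equation on the published sample panel.

    With ``stepwise=False`` the published predictor set for ``kind`` is
    fitted by plain OLS instead of being selected.
    """
    from . import datasets
    panel = published_panel(kind)
    if stepwise:
        return stepwise_fit(panel["ne"], panel[_CANDIDATES], response="NE",
                            alpha_enter=alpha_enter,
                            alpha_remove=alpha_remove,
                            collinearity_alpha=collinearity_alpha)
    import statsmodels.api as sm
    predictors = datasets.printed_equations()[kind].predictors()
    X = sm.add_constant(panel[predictors])
    fitres = sm.OLS(panel["ne"], X).fit()
    return RegressionEquation(
        response="NE",
        terms=[(p, float(fitres.params[p])) for p in predictors],
        intercept=float(fitres.params["const"]),
        r2=float(fitres.rsquared), n=len(panel))
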