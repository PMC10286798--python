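"""End-to-end workflows over the packaged dataset.

Wires the modules together the way the original analysis is structured:

1. calibrate a quantum use efficiency c_ε per LED treatment from its harvest
   dry mass (:func:`calibrate_treatments`);
2. build waveband fraction features from the treatment labels and fit the
   candidate polynomial families (:func:`fit_candidates`);
3. couple a fitted (or the packaged) efficiency model back into the growth
   ODEs and compare predicted harvest mass against observation, with the
   constant-c_ε model as baseline (:func:`coupled_prediction_table`);
4. cross-validate on the greenhouse dataset under natural light
   (:func:`greenhouse_predictions`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import CalibrationProblem, calibrate_all
from .datasets import (
    EnvironmentRecipe,
    build_environment,
    build_greenhouse_environment,
    default_initial_state,
    load_recipes,
    load_treatment_table,
    load_validation_table,
    treatment_features,
)
from .errors import OutOfDomainWarning
from .growth import GrowthParameters, simulate
from .regression import (
    CANDIDATE_TERM_SETS,
    PolynomialEfficiencyModel,
    RegressionModel,
    published_model,
    select_model,
)
from .spectra import BAND_ORDER

__all__ = [
    "calibrate_treatments",
    "fit_candidates",
    "coupled_prediction_table",
    "greenhouse_predictions",
    "DEFAULT_HOLDOUT_TREATMENTS",
]

#: Treatments reserved for testing in the packaged fit (the white-spectrum
#: rows among them are dropped earlier because their labels carry no band
#: decomposition).
DEFAULT_HOLDOUT_TREATMENTS = (7, 14, 19)


def _problem_builder(recipes, params, initial):
    def build(rec: pd.Series) -> CalibrationProblem:
        recipe: EnvironmentRecipe = recipes[rec["source"]]
        env = build_environment(recipe, rec["i_par_fr_w_m2"], rec["pfd_umol_m2_s"])
        return CalibrationProblem(
            target_mass=float(rec["dry_mass_g"]),
            env=env,
            params=recipe.growth_parameters(params),
            initial=initial,
            per_plant=True,
        )

    return build


def calibrate_treatments(
    records: pd.DataFrame | None = None,
    recipes=None,
    params: GrowthParameters | None = None,
    initial=None,
) -> pd.DataFrame:
    """Calibrated c_ε for every treatment row (20 rows; failures reported)."""
    records = load_treatment_table() if records is None else records
    recipes = recipes or load_recipes()
    initial = initial or default_initial_state()
    table = calibrate_all(records, _problem_builder(recipes, params, initial))
    return records.merge(table, on="treatment")


def fit_candidates(
    calibrated: pd.DataFrame | None = None,
    holdout=DEFAULT_HOLDOUT_TREATMENTS,
    normalize: str = "ri",
    penalty: str = "none",
    penalty_weight: float = 0.0,
    feature_kind: str = "irradiance",
) -> tuple[pd.DataFrame, list[RegressionModel]]:
    """Fit the candidate term-set families on the calibrated LED dataset.

    ``calibrated`` defaults to running :func:`calibrate_treatments`.  Only
    label-resolvable treatments enter (white-spectrum rows have no feature
    vector); holdout treatment numbers not present among them are ignored.
    ``feature_kind`` selects irradiance- or PFD-fraction features.
    """
    if calibrated is None:
        calibrated = calibrate_treatments()
    features = treatment_features(calibrated)
    merged = features.merge(
        calibrated[["treatment", "ce_g_per_J", "converged"]], on="treatment"
    )
    merged = merged[merged["converged"]].reset_index(drop=True)
    suffix = "i" if feature_kind == "irradiance" else "pfd"
    frac_cols = [f"f_{name}_{suffix}" for name in BAND_ORDER]
    fractions = merged[frac_cols].to_numpy()
    test_mask = merged["treatment"].isin(holdout).to_numpy()
    table, models = select_model(
        CANDIDATE_TERM_SETS,
        fractions,
        merged["ce_g_per_J"].to_numpy(),
        irradiance_w_m2=merged["i_par_fr_w_m2"].to_numpy(),
        normalize=normalize,
        penalty=penalty,
        penalty_weight=penalty_weight,
        train_idx=np.flatnonzero(~test_mask),
        test_idx=np.flatnonzero(test_mask),
    )
    return table, models


def coupled_prediction_table(
    model: PolynomialEfficiencyModel | None = None,
    records: pd.DataFrame | None = None,
    recipes=None,
    params: GrowthParameters | None = None,
    baseline_ce: float = 17.0e-6,
) -> pd.DataFrame:
    """Spectrum-aware vs constant-efficiency dry-mass predictions.

    For every label-resolvable treatment, predicts c_ε from the label's
    irradiance fractions with ``model`` (default: the packaged published
    model), simulates the treatment's schedule with that c_ε and with the
    constant baseline, and reports both relative errors against the observed
    harvest mass.
    """
    model = model or published_model()
    records = load_treatment_table() if records is None else records
    recipes = recipes or load_recipes()
    features = treatment_features(records)
    initial = default_initial_state()
    rows = []
    for _, rec in features.iterrows():
        source = rec["source"]
        recipe = recipes[source]
        full = records[records["treatment"] == rec["treatment"]].iloc[0]
        env = build_environment(recipe, full["i_par_fr_w_m2"], full["pfd_umol_m2_s"])
        p = recipe.growth_parameters(params)
        fractions = rec[[f"f_{name}_i" for name in BAND_ORDER]].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OutOfDomainWarning)
            ce_pred = model.predict(fractions, rec["i_par_fr_w_m2"])
        obs = float(rec["dry_mass_g"]) * p.plant_density  # g m^-2
        mass_model = float(simulate(initial, env, ce_pred, p).total[-1])
        mass_const = float(simulate(initial, env, baseline_ce, p).total[-1])
        rows.append(
            {
                "treatment": int(rec["treatment"]),
                "label": rec["label"],
                "ce_predicted": ce_pred,
                "observed_g_m2": obs,
                "predicted_g_m2": mass_model,
                "baseline_g_m2": mass_const,
                "rel_error_model": abs(mass_model - obs) / obs,
                "rel_error_baseline": abs(mass_const - obs) / obs,
            }
        )
    return pd.DataFrame(rows)


def greenhouse_predictions(
    model: PolynomialEfficiencyModel | None = None,
    params: GrowthParameters | None = None,
    baseline_ce: float = 17.0e-6,
) -> pd.DataFrame:
    """Dry-mass predictions for the greenhouse validation periods.

    Builds the natural-light schedule for each period from its daily light
    integral, predicts c_ε from the solar-like spectrum's irradiance
    fractions, and simulates to day 35, sampling the observation days.
    Returns one row per period and observation day with the spectrum-aware
    and constant-efficiency predictions alongside the measured mass.
    """
    model = model or published_model()
    recipes = load_recipes()
    recipe = recipes["greenhouse"]
    table = load_validation_table()
    obs_days = [14, 18, 21, 25, 28, 32, 35]
    initial = default_initial_state()
    rows = []
    for _, rec in table.iterrows():
        env, bands = build_greenhouse_environment(recipe, float(rec["dli_mol_m2_d"]))
        p = recipe.growth_parameters(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OutOfDomainWarning)
            ce_pred = model.predict(bands.irradiance_fractions, bands.irradiance_total)
        t_eval = [d * 86400.0 for d in obs_days]
        traj_model = simulate(initial, env, ce_pred, p, t_eval_s=t_eval)
        traj_const = simulate(initial, env, baseline_ce, p, t_eval_s=t_eval)
        for day in obs_days:
            t = day * 86400.0
            i_m = int(np.argmin(np.abs(traj_model.t_s - t)))
            i_c = int(np.argmin(np.abs(traj_const.t_s - t)))
            rows.append(
                {
                    "period": rec["period"],
                    "dli_mol_m2_d": rec["dli_mol_m2_d"],
                    "day": day,
                    "ce_predicted": ce_pred,
                    "observed_g": float(rec[f"day_{day}"]),
                    "predicted_g": float(traj_model.total_per_plant[i_m]),
                    "baseline_g": float(traj_const.total_per_plant[i_c]),
                }
            )
    return pd.DataFrame(rows)
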