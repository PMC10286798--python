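"""Packaged experiment tables, environment recipes and synthetic data.

Ships three kinds of fixtures:

* the 20-treatment LED experiment table (per-plant harvest dry mass, total
  photon flux density and integrated irradiance I_PAR+FR per treatment),
  checksummed so silent edits are caught at load time;
* the greenhouse validation table: harvest dry mass at seven ages for three
  natural-light growing periods with their daily light integrals;
* environment recipes that render the narrative descriptions of the source
  experiments (photoperiods, temperature stages, CO₂) into piecewise-constant
  :class:`~spectragrow.growth.EnvironmentSchedule` objects.  Every recipe
  field that the source descriptions do not state (harvest days for the two
  2020 studies, plant density, the initial seedling state) is listed under
  the recipe's ``assumed`` key.

A seeded synthetic-dataset generator produces fraction/efficiency tables
from a known polynomial model for regression recovery tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataCorruptionError
from .growth import EnvironmentSchedule, GrowthParameters, PlantState
from .regression import PolynomialEfficiencyModel
from .spectra import (
    BAND_ORDER,
    BandSummary,
    integrate_bands,
    parse_treatment_label,
    synth_led_spectrum,
    synth_solar_spectrum,
)

__all__ = [
    "load_treatment_table",
    "load_validation_table",
    "load_recipes",
    "EnvironmentRecipe",
    "build_environment",
    "build_greenhouse_environment",
    "treatment_features",
    "default_initial_state",
    "generate_synthetic_dataset",
    "sample_fractions",
]

_CHECKSUMS = {
    # sha256 of the packaged CSVs; guards against silent fixture corruption.
    "led_treatments.csv": "3dc50698fe178c60c2f98115f949fda65a44b9b2d5e64b1f52ed1fed54414aba",
    "greenhouse_validation.csv": "58700f8afe40a75faa577db8ca18b887bad32552b53637d365303d543c460377",
}

#: Default seedling transplant state: 0.05 g m⁻² total dry mass, 90 %
#: structural / 10 % non-structural.
DEFAULT_INITIAL_TOTAL_G_M2 = 0.05
DEFAULT_STRUCTURAL_SHARE = 0.9

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


def default_initial_state(total_g_m2: float = DEFAULT_INITIAL_TOTAL_G_M2,
                          structural_share: float = DEFAULT_STRUCTURAL_SHARE) -> PlantState:
    """Seedling state at transplant (configurable total and split)."""
    return PlantState(
        x_nsdm=total_g_m2 * (1.0 - structural_share),
        x_sdm=total_g_m2 * structural_share,
    )


def _read_packaged_csv(name: str) -> pd.DataFrame:
    path = resources.files("spectragrow.data").joinpath(name)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise DataCorruptionError(
            f"packaged file {name} checksum mismatch: {digest}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_treatment_table() -> pd.DataFrame:
    """The 20-row LED treatment table.

    Columns: ``treatment`` (1-20), ``source`` (study tag), ``label``
    (e.g. ``B20G20R120FR20``; ``WW``/``EQW`` labels have no band split),
    ``dry_mass_g`` (per plant at harvest), ``pfd_umol_m2_s`` (total photon
    flux density) and ``i_par_fr_w_m2`` (integrated 400-750 nm irradiance;
    treatment 11's source prints a stray ``>`` after 37.3, stored as 37.3).
    """
    return _read_packaged_csv("led_treatments.csv")


def load_validation_table() -> pd.DataFrame:
    """Greenhouse validation: dry mass (g) at days 14-35 for three periods."""
    return _read_packaged_csv("greenhouse_validation.csv")


@dataclass(frozen=True)
class EnvironmentRecipe:
    """A named environment recipe with explicit assumption tracking."""

    name: str
    spec: Mapping

    @property
    def assumed_fields(self) -> tuple[str, ...]:
        return tuple(self.spec.get("assumed", ()))

    @property
    def plant_density(self) -> float:
        return float(self.spec.get("plant_density", 1.0))

    @property
    def harvest_day(self) -> float:
        return float(self.spec.get("harvest_day", self.spec.get("duration_day")))

    @property
    def hydroponic(self) -> bool:
        return bool(self.spec.get("hydroponic", False))

    def growth_parameters(self, base: GrowthParameters | None = None) -> GrowthParameters:
        """Parameters adjusted for the recipe (root fraction, plant density)."""
        p = base or GrowthParameters()
        if self.hydroponic:
            p = p.with_(c_tau=0.14)
        return p.with_(plant_density=self.plant_density)


def load_recipes() -> dict[str, EnvironmentRecipe]:
    """All packaged environment recipes keyed by study tag."""
    path = resources.files("spectragrow.data").joinpath("environment_recipes.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return {name: EnvironmentRecipe(name, spec) for name, spec in raw.items()}


def _daily_segments(day_start: float, day_end: float, photoperiod_h: float,
                    irradiance: float, t_day: float, t_night: float, co2: float):
    """Light/dark alternation for whole days in [day_start, day_end)."""
    segs = []
    day = day_start
    while day < day_end - 1e-9:
        t0 = day * SECONDS_PER_DAY
        if photoperiod_h >= 24:
            segs.append((t0, t0 + SECONDS_PER_DAY, t_day, co2, irradiance))
        else:
            t_light = t0 + photoperiod_h * SECONDS_PER_HOUR
            segs.append((t0, t_light, t_day, co2, irradiance))
            segs.append((t_light, t0 + SECONDS_PER_DAY, t_night, co2, 0.0))
        day += 1.0
    return segs


def _schedule_from_tuples(segs) -> EnvironmentSchedule:
    edges = np.array([segs[0][0]] + [s[1] for s in segs])
    return EnvironmentSchedule(
        edges,
        np.array([s[2] for s in segs]),
        np.array([s[3] for s in segs]),
        np.array([s[4] for s in segs]),
    )


def build_environment(
    recipe: EnvironmentRecipe,
    treatment_irradiance_w_m2: float,
    treatment_pfd_umol_m2_s: float,
) -> EnvironmentSchedule:
    """Render an LED-study recipe into a schedule for one treatment.

    Pre-treatment stages state a PPFD rather than an irradiance; their
    irradiance is the treatment's measured I_PAR+FR scaled by the PPFD ratio
    (i.e. the pre-treatment spectrum is assumed spectrally similar).
    """
    spec = recipe.spec
    if "stages" not in spec:
        raise ConfigError(f"recipe {recipe.name!r} has no stages; use the dedicated builder")
    co2_default = spec.get("co2_ppm")
    segs = []
    for stage in spec["stages"]:
        for key in ("start_day", "end_day", "ppfd", "photoperiod_h", "t_day"):
            if key not in stage:
                raise ConfigError(f"stage in recipe {recipe.name!r} missing {key!r}")
        if stage["ppfd"] == "treatment":
            irr = float(treatment_irradiance_w_m2)
        else:
            irr = (
                float(stage["ppfd"]) / float(treatment_pfd_umol_m2_s)
            ) * float(treatment_irradiance_w_m2)
        co2 = float(stage.get("co2_ppm", co2_default))
        segs.extend(
            _daily_segments(
                float(stage["start_day"]),
                float(stage["end_day"]),
                float(stage["photoperiod_h"]),
                irr,
                float(stage["t_day"]),
                float(stage.get("t_night", stage["t_day"])),
                co2,
            )
        )
    return _schedule_from_tuples(segs)


def build_greenhouse_environment(
    recipe: EnvironmentRecipe, dli_mol_m2_day: float
) -> tuple[EnvironmentSchedule, BandSummary]:
    """Render the greenhouse recipe for one growing period.

    The period's daily light integral is delivered over the recipe's light
    window through a smooth solar-like spectrum; the returned
    :class:`BandSummary` carries that spectrum's waveband integrals for the
    efficiency regression.  Day/night temperature alternation and the CO₂
    enrichment switch take effect after ``switch_day``.
    """
    spec = recipe.spec
    window_h = float(spec["light_window_h"])
    ppfd = dli_mol_m2_day * 1e6 / (window_h * SECONDS_PER_HOUR)
    spectrum = synth_solar_spectrum(ppfd)
    bands = integrate_bands(spectrum)
    irr = bands.irradiance_total
    switch = float(spec["switch_day"])
    duration = float(spec["duration_day"])
    segs = _daily_segments(
        0.0, switch, window_h, irr, float(spec["t_pre"]), float(spec["t_pre"]),
        float(spec["co2_pre_ppm"]),
    )
    segs += _daily_segments(
        switch, duration, window_h, irr, float(spec["t_day"]), float(spec["t_night"]),
        float(spec["co2_ppm"]),
    )
    return _schedule_from_tuples(segs), bands


def treatment_features(records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Waveband features for every label-resolvable treatment.

    For each treatment whose label decomposes into band photon fluxes, a
    narrow-band LED spectrum is synthesized at the labelled band fluxes
    (scaled to the measured total PFD) and integrated into irradiance
    fraction ratios.  Returns one row per resolvable treatment with the four
    PFD fractions, the four irradiance fractions, the measured total
    irradiance, dry mass and source tag.  ``WW``/``EQW`` treatments are
    omitted: their band composition cannot be derived from the label.
    """
    if records is None:
        records = load_treatment_table()
    rows = []
    for _, rec in records.iterrows():
        label = parse_treatment_label(rec["label"])
        if not label.resolvable:
            continue
        scale = float(rec["pfd_umol_m2_s"]) / label.total_pfd
        spectrum = synth_led_spectrum(
            {k: v * scale for k, v in label.band_pfds.items()}
        )
        bands = integrate_bands(spectrum)
        row = {"treatment": int(rec["treatment"]), "source": rec["source"],
               "label": rec["label"], "dry_mass_g": float(rec["dry_mass_g"]),
               "i_par_fr_w_m2": float(rec["i_par_fr_w_m2"])}
        for name, val in zip(BAND_ORDER, label.pfd_fractions):
            row[f"f_{name}_pfd"] = val
        for name, val in zip(BAND_ORDER, bands.irradiance_fractions):
            row[f"f_{name}_i"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def sample_fractions(
    rng: np.random.Generator,
    n: int,
    domain: Mapping[str, tuple[float, float]] | None = None,
    alpha: tuple[float, float, float, float] = (1.6, 1.5, 6.0, 0.8),
) -> np.ndarray:
    """Sample fraction 4-vectors inside a per-band domain.

    Dirichlet draws (red-dominant by default, matching the LED dataset's
    composition) with rejection against the domain box.  Each row sums to one
    by construction.
    """
    if domain is None:
        domain = {"blue": (0.0, 0.421), "green": (0.0, 0.605),
                  "red": (0.254, 1.0), "far_red": (0.0, 0.321)}
    lo = np.array([domain[name][0] for name in BAND_ORDER])
    hi = np.array([domain[name][1] for name in BAND_ORDER])
    out = np.empty((n, 4))
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("fraction sampler rejection rate too high")
        draw = rng.dirichlet(alpha, size=max(n, 16))
        ok = draw[(np.all(draw >= lo, axis=1)) & (np.all(draw <= hi, axis=1))]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_synthetic_dataset(
    model: PolynomialEfficiencyModel,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    irradiance_range: tuple[float, float] = (30.0, 42.0),
    closure_jitter: float = 0.0,
) -> pd.DataFrame:
    """Synthetic fraction/efficiency table drawn from a known model.

    Fractions come from ``sampler`` (default: :func:`sample_fractions` over
    the packaged model's domain), irradiances uniformly from
    ``irradiance_range`` (W m⁻², matching the LED dataset's span), and the
    efficiency target is the model prediction plus Gaussian noise with
    standard deviation ``noise_sd`` (in c_ε units, g J⁻¹).  Deterministic
    given ``seed``; noiseless when ``noise_sd=0``.

    ``closure_jitter`` perturbs each fraction uniformly by up to the given
    amount, emulating fractions obtained from independently integrated
    wavebands, whose sum deviates from one at rounding level.  It must stay
    below the model's closure tolerance (1e-6); the default keeps the
    compositions exactly closed.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    if sampler is None:
        fractions = sample_fractions(rng, n, domain=model.domain)
    else:
        fractions = np.asarray(sampler(rng, n), dtype=float)
        if fractions.shape != (n, 4):
            raise ValueError("sampler must return an (n, 4) array")
        from .regression import _validate_fractions

        for row in fractions:
            _validate_fractions(row)
    if closure_jitter:
        fractions = np.clip(
            fractions + rng.uniform(-closure_jitter, closure_jitter, size=fractions.shape),
            0.0,
            1.0,
        )
    irr = rng.uniform(*irradiance_range, size=n)
    ce = model.predict_many(fractions, irr)
    if noise_sd > 0:
        ce = ce + rng.normal(0.0, noise_sd, size=n)
    df = pd.DataFrame(fractions, columns=[f"f_{name}_i" for name in BAND_ORDER])
    df["i_par_fr_w_m2"] = irr
    df["ce_g_per_J"] = ce
    return df
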