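"""Seeded synthetic-data generators mirroring each experimental assay.

The raw animal recordings behind the analysis chain are not deposited,
so each analysis stage is paired with a generator that embeds known
ground truth with the noise structure the assay exhibits:

* dye-dilution perfusion series — multiplicative Gaussian noise on the
  outflow fluorescence (plate-reader variability), with an
  equilibration ramp over the first 30 min before the analysis windows;
* osmotic-challenge (ΔOsm, Vp) datasets — additive Gaussian scatter on
  a true line Vp = baseline + L_p·A·ΔOsm, with a helper that calibrates
  the noise SD to a target regression R²;
* isotope efflux — Poisson counts around a mono-exponential decay;
* dose-response tables — the four-parameter Hill curve plus additive
  Gaussian noise.

Every generator takes an explicit seed; a fixed seed reproduces the
output bit-for-bit.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import EffluxSeries, hill_equation
from .secretion import OsmoticChallengeDataset, PerfusionTimeSeries

#: study conditions of the reference experiments
DEFAULT_TRUE_VP = 6.8          # µl min⁻¹
DEFAULT_INFUSION_RATE = 9.0    # µl min⁻¹
DEFAULT_EFFLUX_TIMES_S = (0.0, 20.0, 40.0, 60.0, 80.0)
RAMP_END_MIN = 30.0


def gen_perfusion(
    true_vp: float = DEFAULT_TRUE_VP,
    ri: float = DEFAULT_INFUSION_RATE,
    noise_cv: float = 0.03,
    duration_min: float = 120.0,
    seed: Optional[int] = 0,
    ci: float = 1000.0,
    fraction_min: float = 5.0,
    animal_id: str = "sim",
    condition: str = "vehicle",
) -> PerfusionTimeSeries:
    """Simulate a ventriculo-cisternal perfusion dye-dilution series.

    The steady-state outflow fluorescence follows from dye conservation,
    Co = Ci·ri/(ri + Vp); the first 30 min approach it along a
    saturating exponential (mixing of the ventricular dead volume),
    after which the series sits exactly at steady state so that
    noiseless recovery in the standard analysis windows is exact.
    Multiplicative Gaussian noise of coefficient of variation
    ``noise_cv`` perturbs the outflow.
    """
    if true_vp < -ri:
        raise ValueError("true_vp must be >= -ri")
    rng = np.random.default_rng(seed)
    t = np.arange(fraction_min / 2.0, duration_min, fraction_min)
    co_ss = ci * ri / (ri + true_vp)
    ramp = co_ss + (ci - co_ss) * np.exp(-t / (RAMP_END_MIN / 4.0))
    co = np.where(t >= RAMP_END_MIN, co_ss, ramp)
    if noise_cv > 0:
        co = co * (1.0 + noise_cv * rng.standard_normal(co.shape))
        co = np.clip(co, 1e-6 * ci, None)
    return PerfusionTimeSeries(
        time_min=t,
        inflow_fluor=np.full_like(t, ci),
        outflow_fluor=co,
        infusion_rate_ul_min=ri,
        animal_id=animal_id,
        condition=condition,
    )


def noise_sd_for_r2(
    slope: float, osm_offsets: Sequence[float], target_r2: float
) -> float:
    """Noise SD giving an expected regression R² for a known true slope.

    With signal variance s²·Var(x) and independent noise of variance σ²,
    the expected R² is s²Var(x) / (s²Var(x) + σ²); invert for σ.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    var_x = float(np.var(np.asarray(osm_offsets, dtype=float)))
    signal_var = slope**2 * var_x
    return float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))


def gen_osmotic_challenge(
    baseline_vp: float = DEFAULT_TRUE_VP,
    lp: float = 8.333e-5,
    area: float = 4.6,
    osm_offsets: Optional[Sequence[float]] = None,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = 0,
    target_r2: float = 0.48,
) -> OsmoticChallengeDataset:
    """Simulate the per-animal osmotic-challenge dataset.

    The true slope is L_p·A by construction (in µl min⁻¹ mOsm⁻¹:
    lp·area·60).  Defaults emulate the reference experiment: 11 animals
    spanning ±50 mOsm effective ventricular offsets, and noise
    calibrated so the regression R² is ~0.48 in expectation.
    """
    if osm_offsets is None:
        osm_offsets = np.linspace(-50.0, 50.0, 11)
    x = np.asarray(osm_offsets, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 animals")
    slope = lp * area * 60.0  # cm³ s⁻¹ Osm⁻¹·cm² → µl min⁻¹ mOsm⁻¹ per cm² cancels
    if noise_sd is None:
        noise_sd = noise_sd_for_r2(slope, x, target_r2)
    rng = np.random.default_rng(seed)
    vp = baseline_vp + slope * x
    if noise_sd > 0:
        vp = vp + noise_sd * rng.standard_normal(x.shape)
    return OsmoticChallengeDataset(delta_osm_mosm=x, vp_ul_min=vp)


def gen_efflux(
    k_per_min: float = 0.40,
    a0: float = 5000.0,
    times_s: Sequence[float] = DEFAULT_EFFLUX_TIMES_S,
    bg_level: float = 0.0,
    seed: Optional[int] = 0,
    noise: str = "poisson",
    label: str = "sim",
) -> EffluxSeries:
    """Simulate an ⁸⁶Rb⁺ efflux series with ³H-mannitol background.

    Tissue activity decays as a0·e^(−kt); the measured ⁸⁶Rb⁺ channel
    adds an extracellular background of mean ``bg_level`` that the
    mannitol channel reports.  ``noise="poisson"`` draws counts;
    ``noise="none"`` returns the expected values (so the estimator
    round trip is exact).
    """
    if k_per_min < 0:
        raise ValueError("k_per_min must be >= 0")
    t = np.asarray(times_s, dtype=float)
    mean_rb = a0 * np.exp(-k_per_min * t / 60.0) + bg_level
    mean_bg = np.full_like(t, float(bg_level))
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        rb = rng.poisson(mean_rb).astype(float)
        bg = rng.poisson(mean_bg).astype(float)
    elif noise == "none":
        rb, bg = mean_rb, mean_bg
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return EffluxSeries(time_s=t, rb_counts=rb, mannitol_counts=bg, label=label)


def gen_dose_response(
    ic50: float = 10.7,
    hill: float = 1.0,
    ymin: float = 0.0,
    ymax: float = 100.0,
    doses: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = 0,
) -> pd.DataFrame:
    """Forward-evaluate the Hill equation over a dose ladder.

    Defaults emulate an oocyte current-inhibition titration: IC50
    10.7 µM, Hill slope 1, response running 0→100 (% block) over a
    half-log dose ladder.  Additive Gaussian noise of SD ``noise_sd``
    (response units).
    """
    if ymax == ymin:
        raise ValueError("degenerate curve: ymax == ymin")
    if doses is None:
        doses = np.geomspace(0.1, 300.0, 9)
    x = np.asarray(doses, dtype=float)
    y = hill_equation(x, ymin, ymax, ic50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(x.shape)
    return pd.DataFrame({"dose_um": x, "response": y})
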