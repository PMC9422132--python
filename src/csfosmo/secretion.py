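"""CSF secretion analysis from ventriculo-cisternal perfusion records.

Artificial CSF containing an impermeant fluorescent dextran is infused
into a lateral ventricle at rate r_i while fluid is collected from
cisterna magna in 5-min fractions.  Newly secreted CSF dilutes the dye,
so the production rate follows from the inflow/outflow fluorescence
ratio:

    Vp = r_i · (C_i − C_o) / C_o

Window means of the per-fraction Vp give baseline and treatment
estimates; per-animal percent inhibition compares them; and an ordinary
least-squares regression of Vp on the imposed ventricular osmolality
offset yields the slope from which the osmotic water permeability is
derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import stats

# analysis windows (min after infusion start) used in the reference study
BASELINE_WINDOW: Tuple[float, float] = (50.0, 65.0)
TREATMENT_WINDOW: Tuple[float, float] = (100.0, 120.0)
OSMOTIC_WINDOW: Tuple[float, float] = (50.0, 75.0)


class SecretionError(ValueError):
    pass


@dataclass(frozen=True)
class PerfusionTimeSeries:
    """Dye-dilution record: fraction midpoint times and fluorescences."""

    time_min: np.ndarray
    inflow_fluor: np.ndarray
    outflow_fluor: np.ndarray
    infusion_rate_ul_min: float
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        ci = np.asarray(self.inflow_fluor, dtype=float)
        co = np.asarray(self.outflow_fluor, dtype=float)
        if not (len(t) == len(ci) == len(co)):
            raise SecretionError("time/inflow/outflow must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise SecretionError("time_min must be strictly increasing")
        if np.any(co <= 0):
            raise SecretionError("outflow fluorescence must be > 0")
        if not self.infusion_rate_ul_min > 0:
            raise SecretionError("infusion_rate_ul_min must be > 0")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "inflow_fluor", ci)
        object.__setattr__(self, "outflow_fluor", co)


@dataclass(frozen=True)
class SecretionEstimate:
    vp_ul_min: float
    window_min: Tuple[float, float]
    n_points: int
    se: float


@dataclass(frozen=True)
class OsmoticChallengeDataset:
    """Per-animal (ΔOsm, Vp) pairs from the osmotic-challenge series."""

    delta_osm_mosm: np.ndarray
    vp_ul_min: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.delta_osm_mosm, dtype=float)
        y = np.asarray(self.vp_ul_min, dtype=float)
        if len(x) != len(y):
            raise SecretionError("delta_osm and vp must have equal lengths")
        object.__setattr__(self, "delta_osm_mosm", x)
        object.__setattr__(self, "vp_ul_min", y)


@dataclass(frozen=True)
class OsmoticSlopeFit:
    slope_ul_min_mosm: float
    intercept_ul_min: float
    r_squared: float
    slope_se: float
    n: int


def vp_from_dye(ri: float, ci, co):
    """CSF production rate Vp = ri·(ci − co)/co (µl min⁻¹).

    Accepts scalars or arrays for ci/co.  Negative values (net
    absorption) are returned as-is; the caller decides their handling.
    """
    if not ri > 0:
        raise SecretionError("infusion rate must be > 0")
    co_arr = np.asarray(co, dtype=float)
    if np.any(co_arr <= 0):
        raise SecretionError("outflow fluorescence must be > 0")
    out = ri * (np.asarray(ci, dtype=float) - co_arr) / co_arr
    return float(out) if out.ndim == 0 else out


def windowed_vp(
    series: PerfusionTimeSeries, window: Tuple[float, float] = BASELINE_WINDOW
) -> SecretionEstimate:
    """Mean (± SE) per-fraction Vp over an analysis window (inclusive)."""
    start, end = window
    mask = (series.time_min >= start) & (series.time_min <= end)
    n = int(mask.sum())
    if n == 0:
        raise SecretionError(
            f"no samples in window [{start}, {end}] min "
            f"(series spans {series.time_min[0]}–{series.time_min[-1]} min)"
        )
    vp = vp_from_dye(
        series.infusion_rate_ul_min,
        series.inflow_fluor[mask],
        series.outflow_fluor[mask],
    )
    se = float(np.std(vp, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SecretionEstimate(
        vp_ul_min=float(np.mean(vp)), window_min=(start, end), n_points=n, se=se
    )


def _vp_value(x: Union[SecretionEstimate, float]) -> float:
    return x.vp_ul_min if isinstance(x, SecretionEstimate) else float(x)


def percent_inhibition(
    base: Union[SecretionEstimate, float], treat: Union[SecretionEstimate, float]
) -> float:
    """Percent reduction 100·(1 − treat/base); each animal is its own control."""
    b, t = _vp_value(base), _vp_value(treat)
    if b <= 0:
        raise SecretionError(f"baseline must be > 0, got {b}")
    return 100.0 * (1.0 - t / b)


def mean_percent_inhibition(
    pairs: Sequence[Tuple[Union[SecretionEstimate, float], Union[SecretionEstimate, float]]]
) -> Tuple[float, float]:
    """Average per-animal percent inhibition (mean, SEM)."""
    vals = np.array([percent_inhibition(b, t) for b, t in pairs])
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sem


def osmotic_challenge_slope(d: OsmoticChallengeDataset) -> OsmoticSlopeFit:
    """OLS fit of Vp on ΔOsm: slope (µl min⁻¹ mOsm⁻¹), intercept, R², SE."""
    x, y = d.delta_osm_mosm, d.vp_ul_min
    if len(x) < 3:
        raise SecretionError("need at least 3 animals for the regression")
    if np.ptp(x) == 0:
        raise SecretionError("singular design: all ΔOsm values are equal")
    res = stats.linregress(x, y)
    return OsmoticSlopeFit(
        slope_ul_min_mosm=float(res.slope),
        intercept_ul_min=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        n=len(x),
    )
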