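"""Pressure-perturbation-calorimetry data reduction and expansivity models.

Reduction path: spike integration of each pressure pulse against a locally
interpolated baseline gives a per-temperature heat series ΔQ(T) (μJ);
window least-squares slopes of ΔQ/Δp versus T give the pressure derivative
of the mean heat capacity, [δC̄p/δp]_T; the deviation ΔΔQ from the linear
(ideal-mixing) composition line is an excess-property analogue.

Thermodynamic models: the single-population solute expansivity relation

    ΔQ = T·Δp·(α0 − ᾱ)·V_part·g_s

the discrete-hydration-layer model

    ΔQ = T·Δp·x_s·[(n+1)·V_b·α_b − n·V̄_h·ᾱ_h − V_s·α_s] + A′

and the heat-capacity/volume curvature relation [δC̄p/δp]_T = −T·∂²V/∂T².
Temperatures enter these equations in kelvin and pressures in pascal; the
reduction layer stays in °C / bar / μJ as measured.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Thermogram

BAR_TO_PA = 1.0e5


# ---------------------------------------------------------------------------
# ΔQ series and spike integration
# ---------------------------------------------------------------------------

@dataclass
class DeltaQSeries:
    """Per-pulse heats: DataFrame with columns ``temp_C``, ``dq_uJ``,
    ``direction``, ``dp_bar``, ``reliable``; ``label`` names the sample
    (e.g. its mole percent)."""

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        need = {"temp_C", "dq_uJ", "direction", "dp_bar"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"DeltaQSeries missing columns {sorted(missing)}")
        if "reliable" not in self.data.columns:
            self.data["reliable"] = True
        if (self.data["dp_bar"] <= 0).any():
            raise ValueError("pulse magnitudes must be positive")
        for _, grp in self.data.groupby("direction"):
            t = grp["temp_C"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError("temperatures must be strictly increasing within a pulse direction")

    def up(self) -> pd.DataFrame:
        return self.data[self.data["direction"] == "up"]

    def dq_at(self, temp_C: float, direction: str = "up", tol_C: float = 1.0) -> float:
        """ΔQ of the pulse nearest ``temp_C`` (within ``tol_C``)."""
        grp = self.data[self.data["direction"] == direction]
        if grp.empty:
            raise ValueError(f"no {direction}-pulses in series {self.label!r}")
        i = (grp["temp_C"] - temp_C).abs().idxmin()
        if abs(grp.loc[i, "temp_C"] - temp_C) > tol_C:
            raise ValueError(f"no {direction}-pulse within {tol_C} °C of {temp_C} °C in {self.label!r}")
        return float(grp.loc[i, "dq_uJ"])


@dataclass(frozen=True)
class PulseIntegral:
    dq_uJ: float
    t_start_s: float
    t_end_s: float
    temp_C: float
    direction: str
    dp_bar: float
    noise_sd_uW: float
    reliable: bool


def _window_median(tg: Thermogram, t_lo: float, t_hi: float) -> tuple[float, float, float]:
    """(median power, mid time, residual sd) of samples in [t_lo, t_hi)."""
    s = tg.samples
    mask = (s["time_s"] >= t_lo) & (s["time_s"] < t_hi)
    if not mask.any():
        raise ValueError(f"no samples in baseline window [{t_lo}, {t_hi})")
    p = s.loc[mask, "power_uW"].to_numpy()
    t = s.loc[mask, "time_s"].to_numpy()
    return float(np.median(p)), float(0.5 * (t_lo + t_hi)), float(np.std(p))


def integrate_pulse(tg: Thermogram, event_index: int, baseline_window_s: float = 60.0,
                    settle_s: float = 10.0, noise_floor_uW: float = 1e-3) -> PulseIntegral:
    """Integrate one pressure-pulse spike above a locally linear baseline.

    The baseline interpolates linearly between the medians of a pre-event
    window and a post-spike window (each ``baseline_window_s`` long, the
    latter ending just before the next event). Integration runs from the
    event start to return-to-baseline — the first sample whose residual stays
    within 2x the pre-window noise sd (with a small absolute floor) for
    ``settle_s`` — capped at the next event; a spike still off-baseline at
    the cap is flagged unreliable.
    """
    ev = tg.events.iloc[event_index]
    t0 = float(ev["time_s"])
    s = tg.samples
    t = s["time_s"].to_numpy()
    p = s["power_uW"].to_numpy()
    t_next = float(tg.events.iloc[event_index + 1]["time_s"]) if event_index + 1 < len(tg.events) else float(t[-1])
    if t_next <= t0:
        raise ValueError("overlapping events")
    pre_med, pre_mid, noise_sd = _window_median(tg, t0 - baseline_window_s, t0)
    post_med, post_mid, _ = _window_median(tg, t_next - baseline_window_s, t_next)
    slope = (post_med - pre_med) / (post_mid - pre_mid)
    mask = (t >= t0) & (t < t_next)
    tt, pp = t[mask], p[mask]
    baseline = pre_med + slope * (tt - pre_mid)
    resid = pp - baseline
    thresh = max(2.0 * noise_sd, noise_floor_uW)
    # return-to-baseline: after the spike peak, the first sample from which
    # the residual stays within the threshold for settle_s (noise blips before
    # the spike must not truncate the integral, hence the peak anchor)
    dt = np.median(np.diff(tt)) if len(tt) > 1 else 1.0
    need = max(1, int(round(settle_s / dt)))
    within = np.abs(resid) <= thresh
    peak = int(np.argmax(np.abs(resid)))
    end = len(tt)
    reliable = True
    if not within[peak]:
        run = 0
        reliable = False
        for i in range(peak + 1, len(tt)):
            run = run + 1 if within[i] else 0
            if run >= need:
                end = i - need + 2   # include the first at-baseline sample
                reliable = True
                break
    dq = float(np.trapezoid(resid[:end], tt[:end]))
    return PulseIntegral(dq_uJ=dq, t_start_s=t0, t_end_s=float(tt[end - 1]) if end else t0,
                         temp_C=tg.temperature_at(t0), direction=str(ev["direction"]),
                         dp_bar=float(ev["dp_bar"]), noise_sd_uW=noise_sd, reliable=reliable)


def reduce_thermogram(tg: Thermogram, label: str = "", trim: tuple[float, float] | None = (9.0, 61.0),
                      baseline_window_s: float = 60.0) -> DeltaQSeries:
    """One ΔQ entry per annotated pressure event; temperature taken at event
    start. ``trim`` restricts to the usable temperature range (default
    9–61 °C, matching a 7–62 °C schedule whose first and last pulses sit on
    unsettled baseline); pass ``None`` to keep everything."""
    if tg.n_events == 0:
        raise ValueError("thermogram has no annotated pressure events")
    rows = []
    for k in range(tg.n_events):
        pi = integrate_pulse(tg, k, baseline_window_s=baseline_window_s)
        rows.append((pi.temp_C, pi.dq_uJ, pi.direction, pi.dp_bar, pi.reliable))
    df = pd.DataFrame(rows, columns=["temp_C", "dq_uJ", "direction", "dp_bar", "reliable"])
    if trim is not None:
        lo, hi = trim
        df = df[(df["temp_C"] >= lo - 1e-9) & (df["temp_C"] <= hi + 1e-9)].reset_index(drop=True)
    return DeltaQSeries(data=df, label=label)


# ---------------------------------------------------------------------------
# window gradients and ΔΔQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientResult:
    """Least-squares slope of ΔQ/Δp versus T over a temperature window.

    ``slope_uJ_per_bar_K`` is native; entries with r² < 0.8 are flagged
    low-confidence rather than dropped.
    """

    window: tuple[float, float]
    slope_uJ_per_bar_K: float
    intercept_uJ_per_bar: float
    r_squared: float
    n_points: int
    low_confidence: bool = field(default=False)

    @property
    def slope_as_printed(self) -> float:
        """The slope relabelled in the reference table's mJ·bar⁻¹·K⁻¹ unit
        (numerically identical; no conversion is applied)."""
        return self.slope_uJ_per_bar_K


def window_gradient(series: DeltaQSeries, window: tuple[float, float] = (9.0, 35.0),
                    direction: str = "up", r2_flag: float = 0.8) -> GradientResult:
    """Ordinary least squares of ΔQ/Δp on T over entries inside ``window``."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy T_low < T_high")
    grp = series.data[(series.data["direction"] == direction)
                      & (series.data["temp_C"] >= lo - 1e-9)
                      & (series.data["temp_C"] <= hi + 1e-9)]
    if len(grp) < 3:
        raise ValueError(f"need at least 3 points in window {window}, got {len(grp)}")
    x = grp["temp_C"].to_numpy()
    y = (grp["dq_uJ"] / grp["dp_bar"]).to_numpy()
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2) if np.std(y) > 0 else 1.0
    return GradientResult(window=(float(lo), float(hi)), slope_uJ_per_bar_K=float(fit.slope),
                          intercept_uJ_per_bar=float(fit.intercept), r_squared=r2,
                          n_points=len(grp), low_confidence=r2 < r2_flag)


def delta_delta_q(series_by_composition: Mapping[float, "DeltaQSeries | float"],
                  at_T: float = 25.5, direction: str = "up") -> pd.Series:
    """Deviation of ΔQ from the linear composition line between the pure
    endpoints: ΔΔQ(c) = ΔQ(c) − [(1 − c/100)·ΔQ(0) + (c/100)·ΔQ(100)].

    Values may be given as scalars (μJ, already at ``at_T``) or as
    :class:`DeltaQSeries` to be sampled at ``at_T``. Both endpoints (0 and
    100 mol%) must be present.
    """
    def value(c: float) -> float:
        v = series_by_composition[c]
        return v.dq_at(at_T, direction) if isinstance(v, DeltaQSeries) else float(v)

    comps = sorted(series_by_composition)
    if not any(math.isclose(c, 0.0) for c in comps) or not any(math.isclose(c, 100.0) for c in comps):
        raise ValueError("ΔΔQ needs both endpoint compositions (0 and 100 mol%)")
    q0 = value([c for c in comps if math.isclose(c, 0.0)][0])
    q100 = value([c for c in comps if math.isclose(c, 100.0)][0])
    out = {c: value(c) - ((1.0 - c / 100.0) * q0 + (c / 100.0) * q100) for c in comps}
    return pd.Series(out, name="ddq_uJ")


# ---------------------------------------------------------------------------
# expansivity equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpansivityParams:
    """Symbol set of the expansivity models (SI units unless suffixed).

    Single-population relation: ``alpha0``/``alpha_bar`` (K⁻¹) are solvent and
    solute-partial-volume expansivities, ``v_part_m3_per_kg`` the partial
    specific volume and ``g_s_kg`` the solute mass. Hydration-layer model:
    ``x_s``/``x_b``/``x_h`` are mole fractions of solute, bulk and hydration
    solvent (the latter two carried for bookkeeping; the model itself uses
    only ``x_s``), ``v_b/v_h_bar/v_s`` molar volumes (m³·mol⁻¹),
    ``alpha_b/alpha_h_bar/alpha_s`` expansivities (K⁻¹), ``n`` hydration
    waters per solute and ``a_prime_uJ`` a free offset heat.
    """

    T_K: float = 298.65
    dp_bar: float = 4.0
    alpha0: float = 0.0
    alpha_bar: float = 0.0
    v_part_m3_per_kg: float = 0.0
    g_s_kg: float = 0.0
    n: float = 0.0
    x_s: float = 0.0
    x_b: float = 0.0
    x_h: float = 0.0
    v_b: float = 0.0
    v_h_bar: float = 0.0
    v_s: float = 0.0
    alpha_b: float = 0.0
    alpha_h_bar: float = 0.0
    alpha_s: float = 0.0
    a_prime_uJ: float = 0.0

    def __post_init__(self) -> None:
        if self.T_K <= 0 or self.dp_bar <= 0:
            raise ValueError("T_K and dp_bar must be positive")
        for name in ("x_s", "x_b", "x_h"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be a mole fraction in [0, 1]")


def deltaq_from_alpha_bar(p: ExpansivityParams) -> float:
    """Forward single-population relation: ΔQ (μJ) from ᾱ."""
    joules = p.T_K * p.dp_bar * BAR_TO_PA * (p.alpha0 - p.alpha_bar) * p.v_part_m3_per_kg * p.g_s_kg
    return joules * 1.0e6


def alpha_bar_from_deltaq(dq_uJ: float, p: ExpansivityParams) -> float:
    """Invert the single-population relation for the solute partial-volume
    expansivity: ᾱ = α0 − ΔQ / (T·Δp·V_part·g_s)."""
    denom = p.T_K * p.dp_bar * BAR_TO_PA * p.v_part_m3_per_kg * p.g_s_kg
    if denom == 0:
        raise ZeroDivisionError("V_part * g_s must be non-zero")
    return p.alpha0 - (dq_uJ * 1.0e-6) / denom


def eval_hydration_model(p: ExpansivityParams) -> float:
    """Forward hydration-layer model, heat in μJ (per mole of mixture when
    molar volumes are used; the relation is linear so the basis passes
    through): ΔQ = T·Δp·x_s·[(n+1)·V_b·α_b − n·V̄_h·ᾱ_h − V_s·α_s] + A′."""
    bracket = (p.n + 1.0) * p.v_b * p.alpha_b - p.n * p.v_h_bar * p.alpha_h_bar - p.v_s * p.alpha_s
    return p.T_K * p.dp_bar * BAR_TO_PA * p.x_s * bracket * 1.0e6 + p.a_prime_uJ


def invert_hydration_model(dq_uJ: float, p: ExpansivityParams, solve_for: str) -> float:
    """Solve the hydration-layer model linearly for one of ``alpha_h``,
    ``n`` or ``a_prime`` given all the other parameters."""
    core = p.T_K * p.dp_bar * BAR_TO_PA * p.x_s * 1.0e6
    if solve_for == "a_prime":
        bracket = (p.n + 1.0) * p.v_b * p.alpha_b - p.n * p.v_h_bar * p.alpha_h_bar - p.v_s * p.alpha_s
        return dq_uJ - core * bracket
    if solve_for == "alpha_h":
        coeff = core * p.n * p.v_h_bar
        if coeff == 0:
            raise ZeroDivisionError("cannot solve for alpha_h with n * V_h = 0")
        known = core * ((p.n + 1.0) * p.v_b * p.alpha_b - p.v_s * p.alpha_s)
        return (known + p.a_prime_uJ - dq_uJ) / coeff
    if solve_for == "n":
        coeff = core * (p.v_b * p.alpha_b - p.v_h_bar * p.alpha_h_bar)
        if coeff == 0:
            raise ZeroDivisionError("cannot solve for n: the bracket coefficient of n is zero")
        known = core * (p.v_b * p.alpha_b - p.v_s * p.alpha_s)
        return (dq_uJ - p.a_prime_uJ - known) / coeff
    raise ValueError(f"solve_for must be one of alpha_h, n, a_prime; got {solve_for!r}")


# ---------------------------------------------------------------------------
# volume-curvature (heat-capacity pressure derivative) relation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumePolynomial:
    """V(T) as polynomial coefficients c0..ck (T in kelvin)."""

    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ValueError("need at least one coefficient")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def __call__(self, T: float) -> float:
        return float(np.polynomial.polynomial.polyval(T, self.coefficients))


def hepler_gradient(vp: VolumePolynomial, T: float | np.ndarray) -> float | np.ndarray:
    """[δC̄p/δp]_T = −T·d²V/dT², evaluated analytically from the polynomial."""
    d2 = np.polynomial.polynomial.polyder(np.asarray(vp.coefficients), 2)
    out = -np.asarray(T, dtype=float) * np.polynomial.polynomial.polyval(T, d2)
    return float(out) if np.isscalar(T) else out


def hepler_gradient_tabulated(T_K: Sequence[float], v_alpha: Sequence[float]) -> np.ndarray:
    """The first-derivative form −T·d(V_part·ᾱ)/dT from a tabulated product,
    via central finite differences (one-sided at the ends)."""
    T_K = np.asarray(T_K, dtype=float)
    v_alpha = np.asarray(v_alpha, dtype=float)
    if len(T_K) < 3:
        raise ValueError("need at least 3 tabulated points")
    return -T_K * np.gradient(v_alpha, T_K)
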