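"""Melting-temperature analysis of GFP-based thermal-challenge assays.

Gel-quantified GFP signal, normalised to the on-ice aliquot, is fitted
against challenge temperature with a four-parameter logistic (variable
slope):

    y(T) = bottom + (top - bottom) / (1 + exp(h * (T - Tm)))

The inflection point Tm is the apparent melting temperature.  Per-construct
Tm is the mean over biological repeats with SEM = s / sqrt(n) (n > 1 only);
the shift against wild-type carries a quadrature-propagated error,

    SEM_dTm = sqrt(SEM_wt^2 + SEM_variant^2).

A campaign's stabilising/destabilising cut-off is the mean of the
available SEM_dTm values, so calls scale with the campaign's own noise.
The single-temperature screen compares survival after one heat challenge
(relative to wild-type on the same plate) against the lower bound of the
t-based 95% confidence interval of all pooled measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

log = logging.getLogger("memstab")

TEN_TEMP_GRID = (20.0, 30.0, 40.0, 45.0, 50.0, 55.0, 60.0, 70.0, 80.0, 90.0)


def four_pl(temperature, tm, slope, top, bottom):
    """Four-parameter logistic, decreasing in temperature for slope > 0."""
    return bottom + (top - bottom) / (1.0 + np.exp(slope * (temperature - tm)))


@dataclass
class MeltCurve:
    """One repeat of one construct: (temperature, signal) plus on-ice reference."""

    construct: str
    repeat: str
    temperatures: np.ndarray
    signals: np.ndarray
    ice_signal: float

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temperatures.shape != self.signals.shape:
            raise ValueError("temperature and signal arrays differ in shape")
        if len(np.unique(self.temperatures)) < 5:
            raise ValueError(
                f"{self.construct}/{self.repeat}: need >= 5 distinct temperatures"
            )
        if not self.ice_signal > 0:
            raise ValueError(f"{self.construct}/{self.repeat}: on-ice reference "
                             "must be positive")

    def normalised(self) -> np.ndarray:
        return self.signals / self.ice_signal


@dataclass
class MeltFit:
    tm: float
    slope: float
    top: float
    bottom: float
    residual_norm: float
    reliable: bool


class MeltFitError(RuntimeError):
    pass


def fit_melting_curve(curve: MeltCurve) -> MeltFit:
    """Fit the 4PL by multi-start nonlinear least squares.

    Starts: Tm0 at the temperature of half-maximal normalised signal,
    slope0 in {0.2, 0.5, 1.0}, top/bottom from the data extremes.  The fit
    is flagged unreliable when the fitted Tm falls outside the sampled
    temperature range (no transition observed within the grid).
    """
    temps = curve.temperatures
    y = curve.normalised()
    top0, bottom0 = float(y.max()), float(y.min())
    if top0 - bottom0 < 0.05:
        # no transition inside the grid (already fully folded or unfolded):
        # the 4PL is unidentifiable, so flag instead of failing
        return MeltFit(math.nan, 0.0, top0, bottom0, 0.0, reliable=False)
    half = (top0 + bottom0) / 2.0
    tm0 = float(temps[np.argmin(np.abs(y - half))])
    best = None
    for slope0 in (0.2, 0.5, 1.0):
        try:
            popt, _ = curve_fit(
                four_pl, temps, y, p0=[tm0, slope0, top0, bottom0],
                maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(four_pl(temps, *popt) - y))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise MeltFitError(
            f"{curve.construct}/{curve.repeat}: 4PL fit failed to converge "
            f"from all starts (Tm0={tm0}, n={len(temps)})")
    resid, (tm, slope, top, bottom) = best
    # a believable melt: inflection inside the sampled range, signal falling
    # with temperature, and a transition amplitude well above noise level
    reliable = (bool(temps.min() <= tm <= temps.max())
                and slope > 0 and (top - bottom) > 0.2)
    return MeltFit(float(tm), float(slope), float(top), float(bottom),
                   resid, reliable)


@dataclass
class MeltSummary:
    construct: str
    mean_tm: float
    sem_tm: float | None
    n_repeats: int
    delta_tm: float | None = None
    sem_delta_tm: float | None = None
    status: str | None = None


def summarise_tm(fits: list[MeltFit], construct: str = "") -> MeltSummary:
    """Mean Tm over repeats; SEM = sample SD / sqrt(n), absent for n = 1."""
    if not fits:
        raise MeltFitError(f"{construct}: no converged fits to summarise")
    tms = np.array([f.tm for f in fits])
    n = len(tms)
    sem = float(tms.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    return MeltSummary(construct, float(tms.mean()), sem, n)


def delta_tm_with_error(variant: MeltSummary, wildtype: MeltSummary) -> MeltSummary:
    """Tm shift vs wild-type with quadrature-propagated SEM."""
    out = MeltSummary(variant.construct, variant.mean_tm, variant.sem_tm,
                      variant.n_repeats)
    out.delta_tm = variant.mean_tm - wildtype.mean_tm
    if variant.sem_tm is not None and wildtype.sem_tm is not None:
        out.sem_delta_tm = propagate_sem(wildtype.sem_tm, variant.sem_tm)
    return out


def propagate_sem(sem_wt: float, sem_variant: float) -> float:
    """Quadrature combination of wild-type and variant SEMs."""
    return math.sqrt(sem_wt ** 2 + sem_variant ** 2)


def classify_by_delta_tm(summaries: list[MeltSummary],
                         cutoff: float | None = None) -> float:
    """Assign statuses in place; returns the cut-off used.

    The default cut-off is the campaign mean of the available propagated
    SEMs.  |dTm| >= cutoff decides stabilising/destabilising; the band in
    between is neutral.
    """
    if cutoff is None:
        sems = [s.sem_delta_tm for s in summaries if s.sem_delta_tm is not None]
        if not sems:
            raise MeltFitError(
                "no propagated SEMs available to derive a cut-off; "
                "pass an explicit cutoff")
        cutoff = float(np.mean(sems))
    for s in summaries:
        if s.delta_tm is None:
            raise MeltFitError(f"{s.construct}: delta Tm missing")
        if s.delta_tm >= cutoff:
            s.status = "stabilising"
        elif s.delta_tm <= -cutoff:
            s.status = "destabilising"
        else:
            s.status = "neutral"
    log.info("delta-Tm classification cut-off: %.2f degC", cutoff)
    return cutoff


# ---------------------------------------------------------------------------
# Curve table I/O
# ---------------------------------------------------------------------------

def load_melt_curves(path) -> list[MeltCurve]:
    """Curve TSV: construct, repeat, temperature, intensity[, intensity2...].

    On-ice rows carry ``ice`` in the temperature column.  Multiple
    intensity columns per lane (double-banded constructs) are summed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"temperature": str})
    intensity_cols = [c for c in df.columns if c.startswith("intensity")]
    if not intensity_cols:
        raise ValueError(f"curve table {path}: no intensity column")
    df["signal"] = df[intensity_cols].sum(axis=1)
    curves = []
    for (construct, repeat), group in df.groupby(["construct", "repeat"],
                                                 sort=True):
        ice = group[group["temperature"].str.lower() == "ice"]
        if len(ice) != 1:
            raise ValueError(
                f"curve table {path}: {construct}/{repeat} needs exactly one "
                "on-ice row")
        rest = group[group["temperature"].str.lower() != "ice"]
        curves.append(MeltCurve(
            str(construct), str(repeat),
            rest["temperature"].astype(float).to_numpy(),
            rest["signal"].to_numpy(dtype=float),
            float(ice["signal"].iloc[0]),
        ))
    return curves


def analyse_campaign(curves: list[MeltCurve], wildtype: str,
                     cutoff: float | None = None) -> pd.DataFrame:
    """Fit every curve, summarise per construct, call statuses vs wild-type."""
    by_construct: dict[str, list[MeltFit]] = {}
    for curve in curves:
        fit = fit_melting_curve(curve)
        if not fit.reliable:
            log.warning("%s/%s: unreliable fit (Tm %.1f outside grid or "
                        "non-melting); excluded", curve.construct, curve.repeat,
                        fit.tm)
            continue
        by_construct.setdefault(curve.construct, []).append(fit)
    if wildtype not in by_construct:
        raise MeltFitError(f"no reliable fits for wild-type construct "
                           f"{wildtype!r}")
    wt = summarise_tm(by_construct[wildtype], wildtype)
    summaries = []
    for construct in sorted(by_construct):
        if construct == wildtype:
            continue
        s = summarise_tm(by_construct[construct], construct)
        summaries.append(delta_tm_with_error(s, wt))
    used_cutoff = classify_by_delta_tm(summaries, cutoff)
    rows = [{
        "construct": wildtype, "mean_tm": round(wt.mean_tm, 1),
        "sem_tm": None if wt.sem_tm is None else round(wt.sem_tm, 1),
        "n_repeats": wt.n_repeats, "delta_tm": 0.0, "sem_delta_tm": None,
        "status": "wild-type",
    }]
    for s in summaries:
        rows.append({
            "construct": s.construct, "mean_tm": round(s.mean_tm, 1),
            "sem_tm": None if s.sem_tm is None else round(s.sem_tm, 1),
            "n_repeats": s.n_repeats,
            "delta_tm": round(s.delta_tm, 1),
            "sem_delta_tm": None if s.sem_delta_tm is None
            else round(s.sem_delta_tm, 1),
            "status": s.status,
        })
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = used_cutoff
    return out


def single_temperature_screen(measurements: pd.DataFrame,
                              confidence: float = 95.0,
                              cutoff: float | None = None) -> pd.DataFrame:
    """Survival screen at one challenge temperature.

    ``measurements`` columns: construct, survival (heated / on-ice signal,
    relative to wild-type on the same plate).  The hit cut-off is the lower
    bound of the two-sided t confidence interval of the pooled measurement
    mean (overridable); hits have median survival strictly above it.
    """
    if "construct" not in measurements or "survival" not in measurements:
        raise ValueError("screen table needs 'construct' and 'survival' columns")
    pooled = measurements["survival"].to_numpy(dtype=float)
    if len(pooled) < 3:
        raise ValueError(f"need >= 3 pooled measurements, got {len(pooled)}")
    if cutoff is None:
        alpha = 1.0 - confidence / 100.0
        n = len(pooled)
        half_width = (t_dist.ppf(1 - alpha / 2, n - 1)
                      * pooled.std(ddof=1) / math.sqrt(n))
        cutoff = float(pooled.mean() - half_width)
    out = (measurements.groupby("construct", sort=True)["survival"]
           .median().rename("median_survival").reset_index())
    out["hit"] = out["median_survival"] > cutoff
    out.attrs["cutoff"] = cutoff
    log.info("single-temperature screen: cut-off %.3f, %d/%d hits",
             cutoff, int(out["hit"].sum()), len(out))
    return out
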