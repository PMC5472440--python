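"""Kinetic-trace analysis: initial rates, ATPase conversion, coupling.

Sliding is followed by a FRET signal that decays as the octamer moves away
from the labelled DNA end; ATPase activity is followed in a coupled assay
in which each ADP released oxidises one NADH, so the absorbance-proxy
signal falls linearly at a rate proportional to ATP turnover.  An ADP
standard curve measured alongside each experiment converts signal slope to
absolute ATP consumed per unit time.

The coupling-efficiency statistic divides ATP hydrolysed by base pairs
slid; a value of 1 would mean one ATP per base pair, and larger values
quantify futile hydrolysis (sliding uncoupled from the motor cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binding import FitError, FlatResponseError, HillFit, Titration, fit_hill, hill_linearize

__all__ = [
    "AssayTrace",
    "ADPStandard",
    "SigmoidalFit",
    "CouplingReport",
    "RateEstimate",
    "initial_rate",
    "nadh_to_atp",
    "fit_rate_titration",
    "coupling_efficiency",
    "completion_fraction",
    "FULL_SCALE_FU",
]

#: Sliding FRET traces are scaled to this full-scale signal before analysis.
FULL_SCALE_FU = 100_000.0


@dataclass(frozen=True)
class AssayTrace:
    """A time series from a sliding (FRET) or ATPase (NADH) assay."""

    time: np.ndarray
    signal: np.ndarray
    kind: str = "sliding_fret"  # or "atpase_nadh"
    meta: dict = field(default_factory=dict)
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.size != s.size:
            raise ValueError("time and signal must have equal length")
        if t.size < 10:
            raise ValueError("a trace needs at least 10 samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time must start at >= 0 and be strictly increasing")
        if self.kind not in ("sliding_fret", "atpase_nadh"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    def normalised(self) -> "AssayTrace":
        """Rescale a sliding trace to the fixed full scale, recording the factor."""
        peak = float(np.max(np.abs(self.signal)))
        if peak == 0:
            return self
        factor = FULL_SCALE_FU / peak
        return AssayTrace(self.time, self.signal * factor, self.kind,
                          dict(self.meta), self.scale_factor * factor)


@dataclass(frozen=True)
class ADPStandard:
    """Signal change per µM ADP for the coupled ATPase assay."""

    slope: float          # FU per µM ADP (sign per instrument convention)
    nadh_conc: float = 200.0  # µM; assay design constant (200 or 400)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard slope must be nonzero")
        if self.nadh_conc <= 0:
            raise ValueError("nadh_conc must be positive")


@dataclass(frozen=True)
class RateEstimate:
    rate: float           # magnitude, signal units per second
    se: float
    sign: int             # -1 decaying, +1 rising, 0 flat
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class SigmoidalFit:
    """Allosteric sigmoidal fit V = V_max * P^h / (K_half^h + P^h)."""

    V_max: float
    K_half: float
    h: float
    se_V: float
    se_K: float
    se_h: float
    unit: str
    r_squared: float
    zero_activity: bool = False
    preferred_model: str = "sigmoidal"  # or "linear" when a line fits better
    linear_slope: float = float("nan")

    def __post_init__(self) -> None:
        if not self.zero_activity and (self.K_half <= 0 or self.h <= 0):
            raise ValueError("K_half and h must be positive")
        if self.V_max < 0:
            raise ValueError("V_max must be nonnegative")


@dataclass(frozen=True)
class CouplingReport:
    atp_consumed: float
    bp_slid: float
    efficiency: float | None  # ATP per bp; None when fully uncoupled
    fully_uncoupled: bool = False


def initial_rate(trace: AssayTrace, window: tuple[float, float] | None = None,
                 *, min_points: int = 4) -> RateEstimate:
    """Initial velocity as the slope of a linear fit over an early window.

    With no explicit window the default is the first 10% of the time to
    half-completion of the total signal change, widened if needed to hold
    at least ``min_points`` samples.
    """
    t, s = trace.time, trace.signal
    if window is None:
        total = s[-1] - s[0]
        if total == 0:
            t_half = t[-1]
        else:
            crossing = np.nonzero(np.abs(s - s[0]) >= 0.5 * abs(total))[0]
            t_half = t[crossing[0]] if crossing.size else t[-1]
        hi = t[0] + max(0.1 * (t_half - t[0]), 0.0)
        if np.count_nonzero(t <= hi) < min_points:
            hi = t[min(min_points - 1, t.size - 1)]
        window = (float(t[0]), float(hi))
    lo, hi = window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValueError("window lies outside the trace")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < min_points:
        raise ValueError(f"window holds {int(mask.sum())} samples; need {min_points}")
    res = stats.linregress(t[mask], s[mask])
    slope = float(res.slope)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    sign = 0 if slope == 0 else (1 if slope > 0 else -1)
    return RateEstimate(rate=abs(slope), se=se, sign=sign,
                        window=(lo, hi), n_points=int(mask.sum()))


def nadh_to_atp(trace: AssayTrace, standard: ADPStandard,
                enzyme_conc: float | None = None,
                window: tuple[float, float] | None = None) -> dict:
    """Convert an NADH-coupled trace to an absolute ATPase rate.

    Returns a dict with ``rate_uM_per_s`` and, when ``enzyme_conc`` (µM) is
    given, ``rate_per_enzyme`` in s^-1.
    """
    if trace.kind != "atpase_nadh":
        raise ValueError("expected an atpase_nadh trace")
    est = initial_rate(trace, window)
    rate = est.rate / abs(standard.slope)
    out = {"rate_uM_per_s": float(rate), "signal_rate": est}
    if enzyme_conc is not None:
        if enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        out["rate_per_enzyme"] = float(rate / enzyme_conc)
    return out


def fit_rate_titration(rates: Titration, *, noise_floor: float = 1e-3,
                       compare_linear: bool = True,
                       linear_alpha: float = 0.05) -> SigmoidalFit:
    """Fit the allosteric sigmoidal model to an initial-rate titration.

    This is the Hill model with the baseline fixed at zero (no activity at
    zero enzyme).  Flat titrations — inactive complexes — give an explicit
    zero-activity result instead of an error.  When ``compare_linear`` is
    set, a straight line through the origin competes with the sigmoid by
    an extra-sum-of-squares F-test (the line is the nested model); the
    sigmoid is kept only when it improves the fit at significance
    ``linear_alpha``.  Unstimulated (no-nucleosome) ATPase shows a linear
    dependence on protein concentration and is reported as such.
    """
    try:
        hill = fit_hill(rates, fix_F_min=0.0, noise_floor=noise_floor)
    except FlatResponseError:
        return SigmoidalFit(V_max=0.0, K_half=float("nan"), h=float("nan"),
                            se_V=0.0, se_K=float("nan"), se_h=float("nan"),
                            unit=rates.unit, r_squared=float("nan"),
                            zero_activity=True)

    conc, resp = rates.protein_conc, rates.response
    preferred = "sigmoidal"
    lin_slope = float("nan")
    if compare_linear:
        slope = float(np.dot(conc, resp) / np.dot(conc, conc))
        # residuals weighted by the linear prediction: fluorescence noise
        # is multiplicative, so relative residuals are the homoscedastic
        # scale on which the nested F-test is calibrated
        w = 1.0 / np.maximum(slope * conc, 1e-12 * max(abs(slope), 1.0))
        ssr_lin = float(np.sum(((resp - slope * conc) * w) ** 2))
        ssr_sig = float(np.sum(((hill.predict(conc) - resp) * w) ** 2))
        n = conc.size
        df_extra, df_sig = 2, n - 3
        if df_sig > 0 and ssr_sig > 0:
            F = ((ssr_lin - ssr_sig) / df_extra) / (ssr_sig / df_sig)
            p_val = float(stats.f.sf(max(F, 0.0), df_extra, df_sig))
        else:  # saturated fit; keep the sigmoid
            p_val = 0.0
        # a half-saturation point beyond the titrated range means no
        # saturation was observed: the series is operationally linear
        if p_val >= linear_alpha or hill.K_half > conc.max():
            preferred = "linear"
            lin_slope = slope
    return SigmoidalFit(
        V_max=hill.F_max, K_half=hill.K_half, h=hill.h,
        se_V=float("nan"), se_K=hill.se_K, se_h=hill.se_h,
        unit=rates.unit, r_squared=hill.r_squared,
        preferred_model=preferred, linear_slope=lin_slope,
    )


def coupling_efficiency(atp_consumed: float, bp_slid: float) -> CouplingReport:
    """ATP hydrolysed per base pair slid.

    ``bp_slid`` of zero with nonzero ATP means hydrolysis fully uncoupled
    from movement; the report carries a sentinel flag rather than a number.
    """
    if atp_consumed < 0 or bp_slid < 0:
        raise ValueError("inputs must be nonnegative")
    if bp_slid == 0:
        return CouplingReport(atp_consumed=float(atp_consumed), bp_slid=0.0,
                              efficiency=None, fully_uncoupled=True)
    return CouplingReport(atp_consumed=float(atp_consumed),
                          bp_slid=float(bp_slid),
                          efficiency=float(atp_consumed / bp_slid))


def completion_fraction(trace: AssayTrace, t: float, *,
                        plateau_frac: float = 0.1,
                        plateau_tol: float = 0.05) -> float:
    """Fraction of the total signal change reached by time ``t``.

    The plateau is the mean over the final ``plateau_frac`` of the trace and
    must be flat: the signal drift across that tail may not exceed
    ``plateau_tol`` of the total change.  Result is clamped to [0, 1].
    """
    time, sig = trace.time, trace.signal
    if not (time[0] <= t <= time[-1]):
        raise ValueError("t lies outside the trace")
    n_tail = max(int(plateau_frac * time.size), 3)
    tail = sig[-n_tail:]
    plateau = float(tail.mean())
    total = sig[0] - plateau
    if total == 0:
        raise FitError("no signal change: plateau equals the start value")
    if abs(tail[-1] - tail[0]) > plateau_tol * abs(total):
        raise FitError("no plateau detectable at the end of the trace")
    s_t = float(np.interp(t, time, sig))
    frac = (sig[0] - s_t) / total
    return float(min(max(frac, 0.0), 1.0))
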