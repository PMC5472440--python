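"""Cooperative equilibrium-binding analysis.

Implements the Hill model for cooperative binding of a dimeric remodeller
to nucleosomes or DNA, its confirmation by Hill-plot linearisation, and a
two-line intersection estimator for binding stoichiometry from saturation
titrations performed above the dissociation constant.

The Hill response is

    F(P) = F_min + (F_max - F_min) * P^h / (K_half^h + P^h)

with half-saturation constant ``K_half`` (in the concentration unit of the
input) and Hill coefficient ``h``.  Stoichiometry is read from a titration
at high, fixed ligand concentration [N]: the response rises linearly while
binding sites remain free and is flat once saturated; the two straight
lines intersect at concentration (Y1 - Y2)/(S2 - S1), and dividing by [N]
gives the number of complexes bound per ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "Titration",
    "HillFit",
    "StoichiometryFit",
    "HillPlot",
    "FitError",
    "FlatResponseError",
    "hill_response",
    "fit_hill",
    "hill_linearize",
    "fit_stoichiometry",
]


class FitError(RuntimeError):
    """A model fit failed or its preconditions were not met."""


class FlatResponseError(FitError):
    """The response range is below the noise floor (no binding signal)."""


@dataclass(frozen=True)
class Titration:
    """An ordered concentration–response series at fixed ligand concentration.

    ``protein_conc`` must be strictly positive and strictly increasing
    within each replicate; ``response`` is a dimensionless signal (fraction
    bound, normalised fluorescence, or an initial rate).  ``unit`` names
    the concentration unit and is carried through every downstream fit.
    """

    protein_conc: np.ndarray
    response: np.ndarray
    ligand_conc: float | None = None
    unit: str = "nM"
    replicate_id: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = np.asarray(self.protein_conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "protein_conc", conc)
        object.__setattr__(self, "response", resp)
        if conc.shape != resp.shape:
            raise ValueError("protein_conc and response must have equal length")
        if np.any(conc <= 0):
            raise ValueError("protein concentrations must be strictly positive")
        if self.replicate_id is None:
            if np.any(np.diff(conc) <= 0):
                raise ValueError("concentrations must be strictly increasing")
        else:
            rep = np.asarray(self.replicate_id)
            object.__setattr__(self, "replicate_id", rep)
            if rep.shape != conc.shape:
                raise ValueError("replicate_id must match series length")
            for r in np.unique(rep):
                if np.any(np.diff(conc[rep == r]) <= 0):
                    raise ValueError(
                        "concentrations must be strictly increasing within a replicate"
                    )
        if self.ligand_conc is not None and self.ligand_conc <= 0:
            raise ValueError("ligand_conc must be positive")

    def __len__(self) -> int:
        return self.protein_conc.size


@dataclass(frozen=True)
class HillFit:
    """Fitted cooperative-binding parameters, in the unit of the input."""

    K_half: float
    h: float
    F_min: float
    F_max: float
    se_K: float
    se_h: float
    unit: str
    r_squared: float
    redchi: float

    def __post_init__(self) -> None:
        if self.K_half <= 0 or self.h <= 0:
            raise ValueError("K_half and h must be positive")
        if self.F_max < self.F_min:
            raise ValueError("F_max must be >= F_min")

    def predict(self, P) -> np.ndarray:
        return hill_response(P, self.K_half, self.h, self.F_min, self.F_max)


@dataclass(frozen=True)
class StoichiometryFit:
    """Two-line saturation fit and the implied binding stoichiometry."""

    Y1: float
    S1: float
    Y2: float
    S2: float
    breakpoint_conc: float
    ratio: float
    ligand_conc: float
    unit: str
    n_unsaturated: int
    n_saturated: int


@dataclass(frozen=True)
class HillPlot:
    """Hill-plot regression: log(theta/(1-theta)) vs log(P)."""

    slope: float
    intercept: float
    se_slope: float
    n_retained: int
    retained_mask: np.ndarray


def hill_response(P, K_half: float, h: float, F_min: float = 0.0,
                  F_max: float = 1.0):
    """Evaluate the Hill binding curve at concentration(s) ``P``.

    Monotone nondecreasing in P; returns the midpoint response at
    P = K_half for any h.
    """
    if K_half <= 0:
        raise ValueError("K_half must be positive")
    if h <= 0:
        raise ValueError("h must be positive")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("concentrations must be nonnegative")
    theta = np.where(P > 0, P**h / (K_half**h + P**h), 0.0)
    out = F_min + (F_max - F_min) * theta
    return out if out.ndim else float(out)


def _pooled(titration: Titration) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(titration.protein_conc, kind="stable")
    return titration.protein_conc[order], titration.response[order]


def fit_hill(titration: Titration, *, fix_F_min: float | None = None,
             noise_floor: float = 1e-3) -> HillFit:
    """Least-squares fit of the Hill model to a binding titration.

    Requires at least 6 distinct concentrations spanning the transition.
    A response range below ``noise_floor`` (relative to the signal scale)
    raises :class:`FlatResponseError` — the behaviour wanted for inactive
    complexes whose titrations carry no binding signal.  Fitting is
    unweighted with multi-start initialisation: K_half is seeded at the
    concentration of the response midpoint, h at 1 and at 2.
    """
    conc, resp = _pooled(titration)
    if np.unique(conc).size < 6:
        raise FitError("need at least 6 distinct concentrations")
    scale = max(np.max(np.abs(resp)), 1.0)
    rng_span = resp.max() - resp.min()
    if rng_span < noise_floor * scale:
        raise FlatResponseError(
            f"response range {rng_span:.3g} below noise floor "
            f"{noise_floor * scale:.3g}: no detectable transition"
        )

    # K seed: concentration at which the response crosses its midpoint
    mid = 0.5 * (resp.min() + resp.max())
    k_seed = float(conc[np.argmin(np.abs(resp - mid))])
    k_seed = min(max(k_seed, conc.min()), conc.max())

    def resid(params):
        return hill_response(conc, params["K_half"].value, params["h"].value,
                             params["F_min"].value, params["F_max"].value) - resp

    best = None
    for h0 in (1.0, 2.0):
        params = lmfit.Parameters()
        params.add("K_half", value=k_seed, min=conc.min() * 1e-3,
                   max=conc.max() * 1e3)
        params.add("h", value=h0, min=0.05, max=10.0)
        if fix_F_min is None:
            params.add("F_min", value=float(resp.min()))
        else:
            params.add("F_min", value=float(fix_F_min), vary=False)
        params.add("F_max", value=float(resp.max()))
        try:
            res = lmfit.minimize(resid, params, method="least_squares",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - lmfit internal failure
            raise FitError(f"Hill fit failed: {exc}") from exc
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitError("Hill fit did not converge")

    p = best.params
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - best.chisqr / ss_tot if ss_tot > 0 else np.nan
    se = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
          for k in ("K_half", "h")}
    return HillFit(
        K_half=float(p["K_half"].value), h=float(p["h"].value),
        F_min=float(p["F_min"].value), F_max=float(p["F_max"].value),
        se_K=float(se["K_half"]), se_h=float(se["h"]),
        unit=titration.unit, r_squared=r2, redchi=float(best.redchi),
    )


def hill_linearize(titration: Titration, fit: HillFit, *,
                   theta_lo: float = 0.1, theta_hi: float = 0.9) -> HillPlot:
    """Hill-plot linearisation: slope confirms the fitted Hill coefficient.

    Fractional saturation theta is computed from the fitted amplitudes;
    points with theta outside the (theta_lo, theta_hi) retention band are
    excluded — extremes of the range distort the plot and are conventionally
    dropped.  Ordinary least squares on the retained points.
    """
    conc, resp = _pooled(titration)
    span = fit.F_max - fit.F_min
    if span <= 0:
        raise FitError("degenerate fit amplitudes")
    theta = (resp - fit.F_min) / span
    mask = (theta >= theta_lo) & (theta <= theta_hi)
    if mask.sum() < 3:
        raise FitError(f"only {int(mask.sum())} points in the retention band; need 3")
    x = np.log(conc[mask])
    y = np.log(theta[mask] / (1.0 - theta[mask]))
    n = x.size
    A = np.vstack([x, np.ones(n)]).T
    coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if n > 2 and res_ss.size:
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_slope = float(np.sqrt(res_ss[0] / (n - 2) / sxx))
    else:
        se_slope = 0.0
    return HillPlot(slope=slope, intercept=intercept, se_slope=se_slope,
                    n_retained=int(n), retained_mask=mask)


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    ssr = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(intercept), float(slope), ssr


def fit_stoichiometry(titration: Titration, *, min_points: int = 2,
                      parallel_tol: float = 1e-9) -> StoichiometryFit:
    """Breakpoint stoichiometry from a saturation titration.

    The titration (fixed ligand concentration well above K_d) is split into
    an unsaturated prefix and a saturated suffix; the split index is chosen
    by minimising the total squared residual of the two straight-line fits
    over all admissible partitions.  The intersection concentration
    (Y1 - Y2)/(S2 - S1) divided by the ligand concentration is the binding
    stoichiometry.
    """
    if titration.ligand_conc is None:
        raise FitError("saturation titration requires a ligand concentration")
    conc, resp = _pooled(titration)
    n = conc.size
    if n < 2 * min_points:
        raise FitError("too few points to identify two segments")

    best = None
    for k in range(min_points, n - min_points + 1):
        # each segment must span at least two distinct concentrations
        if np.unique(conc[:k]).size < 2 or np.unique(conc[k:]).size < 2:
            continue
        y1, s1, ssr1 = _line_fit(conc[:k], resp[:k])
        y2, s2, ssr2 = _line_fit(conc[k:], resp[k:])
        total = ssr1 + ssr2
        if best is None or total < best[0]:
            best = (total, k, y1, s1, y2, s2)
    if best is None:
        raise FitError("no admissible two-segment partition")
    _, k, Y1, S1, Y2, S2 = best

    scale = max(abs(S1), abs(S2), 1e-30)
    if abs(S1 - S2) < parallel_tol * scale or abs(S1 - S2) == 0.0:
        raise FitError("segments are parallel: no intersection")
    breakpoint = (Y1 - Y2) / (S2 - S1)
    if not (0.1 * conc.min() <= breakpoint <= 10 * conc.max()):
        warnings.warn(
            f"breakpoint {breakpoint:.3g} {titration.unit} lies far outside "
            f"the titrated range [{conc.min():.3g}, {conc.max():.3g}]",
            stacklevel=2,
        )
    return StoichiometryFit(
        Y1=Y1, S1=S1, Y2=Y2, S2=S2,
        breakpoint_conc=float(breakpoint),
        ratio=float(breakpoint / titration.ligand_conc),
        ligand_conc=float(titration.ligand_conc),
        unit=titration.unit,
        n_unsaturated=int(k), n_saturated=int(n - k),
    )
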