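"""Punnett-square mixture model for dimer species activities.

When two protomer species are co-assembled they pair at random, so a 1:1
mixture of wild type and motor-dead protomers yields wild-type homodimer,
heterodimer and dead homodimer at 1:2:1 — a Punnett square.  Per-dimer
activity rules then give the expected ensemble sliding and ATPase rates:
a dimer needs only one functional motor to slide, but a single-motor
dimer is productive in just one of its two binding orientations, so the
heterodimer contributes half the wild-type rate on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .binding import Titration, hill_response
from .presets import activity_preset, species_preset

__all__ = [
    "SpeciesMix",
    "DimerDistribution",
    "ActivityRules",
    "dimer_distribution",
    "predict_activity",
    "mixture_titration",
    "default_rules",
]

DimerType = tuple[str, str]


def _key(a: str, b: str) -> DimerType:
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class SpeciesMix:
    """Protomer species fractions; must be nonnegative and sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("empty mixture")
        vals = np.array(list(self.fractions.values()), float)
        if np.any(vals < 0):
            raise ValueError("fractions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {vals.sum():.6g}, not 1")
        for name in self.fractions:
            species_preset(name)  # validates the label

    @classmethod
    def parse(cls, text: str) -> "SpeciesMix":
        """Parse ``"WT=0.5,EA=0.5"`` style mixture strings."""
        out: dict[str, float] = {}
        for part in text.split(","):
            name, _, val = part.partition("=")
            out[name.strip()] = float(val)
        return cls(out)


@dataclass(frozen=True)
class DimerDistribution:
    """Random-pairing probabilities over unordered dimer types."""

    probabilities: dict[DimerType, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dimer probabilities sum to {total:.6g}, not 1")

    def __getitem__(self, pair: DimerType) -> float:
        return self.probabilities.get(_key(*pair), 0.0)


@dataclass(frozen=True)
class ActivityRules:
    """Relative sliding / ATPase activity per dimer type (WT homodimer = 1)."""

    sliding: dict[DimerType, float]
    atpase: dict[DimerType, float]

    def require(self, dist: DimerDistribution) -> None:
        for pair, p in dist.probabilities.items():
            if p > 0 and (pair not in self.sliding or pair not in self.atpase):
                raise KeyError(f"no activity rule for dimer type {pair}")


def dimer_distribution(mix: SpeciesMix) -> DimerDistribution:
    """Hardy–Weinberg-style random pairing: p(i,j) = 2 f_i f_j, p(i,i) = f_i²."""
    probs: dict[DimerType, float] = {}
    names = sorted(mix.fractions)
    for a, b in combinations_with_replacement(names, 2):
        fa, fb = mix.fractions[a], mix.fractions[b]
        probs[_key(a, b)] = fa * fb if a == b else 2.0 * fa * fb
    return DimerDistribution(probs)


def default_rules(species: list[str] | None = None, *,
                  heterodimer_mode: str = "orientation") -> ActivityRules:
    """Build per-dimer activity rules from the species attributes.

    Sliding: zero without a functional motor; a single-motor dimer slides
    at half the wild-type rate.  ``heterodimer_mode`` selects between the
    two readings consistent with the mixture data — "orientation" (half of
    bindings productive at full rate) and "uniform" (every single-motor
    dimer at half rate); both give the same expectation.  ATPase scales
    with the number of active motors.  Dimers lacking both CTDs inherit
    the CTD-deletion preset factors multiplicatively: sliding x0.2,
    ATPase x2.
    """
    if heterodimer_mode not in ("orientation", "uniform"):
        raise ValueError("heterodimer_mode must be 'orientation' or 'uniform'")
    if species is None:
        species = ["WT", "EA", "WTdCTD", "EAdCTD"]
    sliding: dict[DimerType, float] = {}
    atpase: dict[DimerType, float] = {}
    for a, b in combinations_with_replacement(sorted(species), 2):
        attrs = (species_preset(a), species_preset(b))
        n_motor = sum(s["motor_active"] for s in attrs)
        n_ctd = sum(s["ctd_present"] for s in attrs)
        slide = {0: 0.0, 1: 0.5, 2: 1.0}[n_motor]
        atp = n_motor / 2.0
        if n_ctd == 0:
            slide *= 0.2
            atp *= 2.0
        sliding[_key(a, b)] = slide
        atpase[_key(a, b)] = atp
    return ActivityRules(sliding=sliding, atpase=atpase)


def predict_activity(dist: DimerDistribution,
                     rules: ActivityRules | None = None) -> dict[str, float]:
    """Expected ensemble activities (relative to pure WT) under random pairing."""
    if rules is None:
        rules = default_rules()
    rules.require(dist)
    slide = sum(p * rules.sliding[pair]
                for pair, p in dist.probabilities.items())
    atp = sum(p * rules.atpase[pair]
              for pair, p in dist.probabilities.items())
    return {"sliding": float(slide), "atpase": float(atp)}


def mixture_titration(mix: SpeciesMix, rules: ActivityRules | None = None,
                      conc: np.ndarray | None = None, *,
                      activity: str = "sliding",
                      preset: str = "WT_sliding") -> Titration:
    """Predicted initial-rate titration for a protomer mixture.

    Composes dimer occupancy of the nucleosome (cooperative binding curve
    from the activity preset) with the Punnett expectation, yielding a
    noiseless rate titration on the same axes the rate fitter consumes.
    The plateau equals ``predict_activity`` times the pure-WT maximal rate.
    """
    cfg = activity_preset(preset)
    if conc is None:
        conc = cfg["K_half"] * 2.0 ** np.arange(-3, 4, dtype=float)
    conc = np.asarray(conc, float)
    rel = predict_activity(dimer_distribution(mix), rules)[activity]
    occupancy = hill_response(conc, cfg["K_half"], cfg["h"], 0.0, 1.0)
    rates = cfg["V_max"] * rel * occupancy
    return Titration(conc, rates, unit=cfg.get("unit", "nM"),
                     meta={"mixture": dict(mix.fractions), "activity": activity,
                           "relative_plateau": rel, "preset": preset})
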