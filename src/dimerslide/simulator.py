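"""Stochastic simulation of nucleosome sliding by a dimeric remodeller.

Model
-----
A nucleosome wraps 147 bp; the DNA beyond the wrap forms a left and a
right flank, named in ``aNb`` form (``0N100`` = no left flank, 100 bp
right flank).  The remodeller is a dimer of two protomers, each carrying
(or lacking) a functional ATPase motor and a C-terminal DNA-binding domain
(CTD).  The dimer senses the length of both flanks out to roughly 50 bp
and biases stepping so that the shorter flank grows — nucleosomes are
pushed away from DNA ends and come to rest where neither end is sensed.

Stepping is simulated per molecule as a continuous-time Markov chain with
1 bp elementary steps and three channels:

* **drift** — while at least one flank is within the sensing range
  (shorter flank <= ``s_sense``), coupled stepping that grows the shorter
  flank at rate ``k_step0 * max(0, sigma(l_long) - sigma(l_short))``,
  where ``sigma`` is a logistic in flank length with midpoint ``s_sense``
  and width ``sense_width``.  Rates are proportionately reduced for short
  flanks and the drive vanishes as the flanks balance.
* **blind** — once *both* flanks strictly exceed the sensing midpoint the
  dimer detects neither end; the two protomers engage in a tug-of-war and
  the nucleosome steps without direction at ``k_step0 / 2`` per direction.
  A nucleosome centred with 50 bp flanks therefore stays put, while one
  with 60 bp flanks is mobilised and wanders until a flank shortens back
  into sensing range.
* **leak** — optional undirected stepping at ``k_leak`` when both motor
  channels are silent (exposed for sub-well oscillation studies; 0 in the
  shipped presets).

A 10 bp phasing landscape (the strong-positioning sequence repeats every
helical turn) provides preferred wells in register with the start
position.  Whenever a step crosses into a well while both flanks satisfy
the sensing criterion — and the step grew the shorter flank, i.e. the
crossing was balance-restoring — the molecule arrests with probability
``p_arrest``; this progressive, probabilistic stop reproduces the
laddered gel products (one extra band per 20 bp of extra starting
overhang) and, by the direction condition, forbids settling more than
one well beyond the DNA centre.

Each active motor hydrolyses ATP at ``k_atp`` per second whenever bound,
whether or not it steps.  Motor-driven steps debit the same ledger, so
the ATP count dominates the coupled step count for every molecule; the
surplus is futile hydrolysis, and sliding becomes progressively
uncoupled as it approaches its end point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .presets import simulator_preset, species_preset

__all__ = [
    "FOOTPRINT_BP",
    "NucleosomeSubstrate",
    "DimerSpec",
    "SimParams",
    "Trajectory",
    "TrajectoryEnsemble",
    "BandPattern",
    "parse_substrate",
    "make_dimer",
    "params_for_dimer",
    "simulate",
    "band_pattern",
    "band_pattern_from_offsets",
    "fret_proxy",
    "sensing_range",
]

FOOTPRINT_BP = 147

_SUBSTRATE_RE = re.compile(r"^(\d+)N(\d+)$")


@dataclass(frozen=True)
class NucleosomeSubstrate:
    """DNA geometry: flank lengths around the 147 bp octamer footprint."""

    left_flank: int
    right_flank: int
    footprint: int = FOOTPRINT_BP

    def __post_init__(self) -> None:
        if self.left_flank < 0 or self.right_flank < 0:
            raise ValueError("flank lengths must be nonnegative")
        if self.footprint < 1:
            raise ValueError("footprint must be positive")

    @property
    def name(self) -> str:
        return f"{self.left_flank}N{self.right_flank}"

    @property
    def dna_length(self) -> int:
        return self.left_flank + self.footprint + self.right_flank

    @property
    def total_flank(self) -> int:
        return self.left_flank + self.right_flank


def parse_substrate(name: str) -> NucleosomeSubstrate:
    """Parse an ``aNb`` substrate name, e.g. ``"0N100"`` or ``"50N50"``."""
    m = _SUBSTRATE_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed substrate name {name!r}; expected e.g. '0N100'")
    return NucleosomeSubstrate(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class DimerSpec:
    """Two protomers and, for single-motor dimers, the bound orientation.

    ``orientation`` is only meaningful when exactly one protomer carries an
    active motor: the dimer is productive for sliding in one of its two
    binding modes.  ``None`` means the orientation is drawn uniformly at
    binding for each molecule.
    """

    protomer_a: str
    protomer_b: str
    orientation: str | None = None  # "productive" | "unproductive" | None

    def __post_init__(self) -> None:
        for p in (self.protomer_a, self.protomer_b):
            species_preset(p)  # validates the label
        if self.orientation is not None:
            if self.orientation not in ("productive", "unproductive"):
                raise ValueError("orientation must be 'productive' or 'unproductive'")
            if self.n_active_motors != 1:
                raise ValueError(
                    "orientation is defined only for single-active-motor dimers"
                )

    @property
    def motor_active(self) -> tuple[bool, bool]:
        return (species_preset(self.protomer_a)["motor_active"],
                species_preset(self.protomer_b)["motor_active"])

    @property
    def ctd_present(self) -> tuple[bool, bool]:
        return (species_preset(self.protomer_a)["ctd_present"],
                species_preset(self.protomer_b)["ctd_present"])

    @property
    def n_active_motors(self) -> int:
        return sum(self.motor_active)

    @property
    def n_ctds(self) -> int:
        return sum(self.ctd_present)


def make_dimer(a: str, b: str = None, orientation: str | None = None) -> DimerSpec:
    return DimerSpec(a, b if b is not None else a, orientation)


@dataclass(frozen=True)
class SimParams:
    """Rate-law parameters for the sliding simulator (rates >= 0, bp, s)."""

    k_step0: float = 1.0
    s_sense: float = 50.0
    sense_width: float = 8.0
    k_atp: float = 20.0 / 9.0
    p_arrest: float = 0.2
    well_period: int = 10
    well_depth: float = 0.0
    k_leak: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_step0", "s_sense", "sense_width", "k_atp", "k_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.p_arrest <= 1.0:
            raise ValueError("p_arrest must lie in [0, 1]")
        if self.well_period < 1:
            raise ValueError("well_period must be >= 1")
        if not 0.0 <= self.well_depth < 1.0:
            raise ValueError("well_depth must lie in [0, 1)")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimParams":
        cfg = simulator_preset(name)
        cfg.update(overrides)
        return cls(**cfg)

    def sigma(self, flank) -> np.ndarray:
        """Soft flank-sensing saturation function (logistic)."""
        if self.sense_width == 0:
            return np.where(np.asarray(flank, float) >= self.s_sense, 1.0, 0.0)
        x = (np.asarray(flank, float) - self.s_sense) / self.sense_width
        return 1.0 / (1.0 + np.exp(-x))


def params_for_dimer(dimer: DimerSpec, base: str = "WT", **overrides) -> SimParams:
    """Resolve rate parameters from the dimer's domain composition.

    A dimer with both CTDs senses flanks with the wild-type range; losing
    both CTDs shortens the range, slows coupled stepping five-fold, doubles
    ATP turnover and adds a residual undirected step channel.  Single-CTD
    dimers are treated as wild-type-like (the CTD acts in trans).
    """
    preset = base if dimer.n_ctds >= 1 else "dCTD"
    return SimParams.from_preset(preset, **overrides)


@dataclass(frozen=True)
class Trajectory:
    """Event-time record for one molecule (piecewise-constant position)."""

    times: np.ndarray        # event times, starting at 0
    dyad: np.ndarray         # absolute dyad position after each event
    atp: np.ndarray          # cumulative ATP hydrolysed at each event time
    coupled_steps: int
    arrested: bool
    productive: bool

    def dyad_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        return self.dyad[np.clip(idx, 0, self.dyad.size - 1)]

    def atp_at(self, t) -> np.ndarray:
        """Cumulative ATP at time t (linear interpolation between events)."""
        return np.interp(np.asarray(t, float), self.times, self.atp)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    substrate: NucleosomeSubstrate
    dimer: DimerSpec
    params: SimParams
    t_end: float
    seed: int
    trajectories: tuple[Trajectory, ...]

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def start_dyad(self) -> int:
        return self.substrate.left_flank + (self.substrate.footprint - 1) // 2

    @property
    def centre(self) -> float:
        return (self.substrate.dna_length - 1) / 2.0

    @property
    def final_dyad(self) -> np.ndarray:
        return np.array([tr.dyad[-1] for tr in self.trajectories], float)

    @property
    def displacement(self) -> np.ndarray:
        return self.final_dyad - self.start_dyad

    @property
    def offsets_from_centre(self) -> np.ndarray:
        return self.final_dyad - self.centre

    @property
    def final_atp(self) -> np.ndarray:
        return np.array([tr.atp[-1] for tr in self.trajectories], float)

    @property
    def coupled_steps(self) -> np.ndarray:
        return np.array([tr.coupled_steps for tr in self.trajectories], int)

    @property
    def arrested(self) -> np.ndarray:
        return np.array([tr.arrested for tr in self.trajectories], bool)

    def dyad_at(self, t) -> np.ndarray:
        return np.array([tr.dyad_at(t) for tr in self.trajectories], float)

    def atp_at(self, t) -> np.ndarray:
        return np.array([tr.atp_at(t) for tr in self.trajectories], float)

    def mean_abs_displacement(self) -> float:
        return float(np.mean(np.abs(self.displacement)))


def _simulate_one(sub: NucleosomeSubstrate, dimer: DimerSpec, params: SimParams,
                  t_end: float, rng: np.random.Generator) -> Trajectory:
    l0, r0 = sub.left_flank, sub.right_flank
    n_motors = dimer.n_active_motors
    if n_motors == 1:
        if dimer.orientation is None:
            productive = bool(rng.random() < 0.5)
        else:
            productive = dimer.orientation == "productive"
    else:
        productive = n_motors == 2
    start_dyad = sub.left_flank + (sub.footprint - 1) // 2
    r_atp = n_motors * params.k_atp

    d = 0  # displacement from the start position, +1 = dyad moves right
    t = 0.0
    atp = 0.0
    coupled = 0
    arrested = False
    last_well = 0  # well of the last arrest evaluation (start position)
    times = [0.0]
    dyads = [start_dyad]
    atps = [0.0]

    def record() -> None:
        times.append(t)
        dyads.append(start_dyad + d)
        atps.append(atp)

    def at_well(disp: int) -> bool:
        return disp % params.well_period == 0

    max_events = 200_000
    for _ in range(max_events):
        left = l0 + d
        right = r0 - d
        if arrested or not productive:
            p_right = p_left = 0.0
            motorised = 0.0
            drift = 0.0
        else:
            if min(left, right) > params.s_sense:
                # Neither end is sensed: undirected stepping at the full
                # motor rate (tug-of-war between the two protomers).
                drift = 0.0
                p_right = p_left = 0.5 * params.k_step0
            else:
                # A sensed end drives stepping that grows the shorter flank.
                s_l = float(params.sigma(left))
                s_r = float(params.sigma(right))
                drift = params.k_step0 * abs(s_r - s_l)
                p_right = drift if s_r > s_l else 0.0
                p_left = drift if s_l > s_r else 0.0
            if params.well_depth > 0 and at_well(d):
                p_right *= 1.0 - params.well_depth
                p_left *= 1.0 - params.well_depth
            motorised = p_right + p_left
            if params.k_leak > 0 and motorised == 0.0:
                p_right += 0.5 * params.k_leak
                p_left += 0.5 * params.k_leak
            # boundary: flanks cannot go negative
            if right == 0:
                p_right = 0.0
            if left == 0:
                p_left = 0.0
        prop = p_right + p_left
        if prop <= 0.0:
            atp += rng.poisson(r_atp * (t_end - t)) if r_atp > 0 else 0.0
            t = t_end
            record()
            break
        dt = rng.exponential(1.0 / prop)
        if t + dt >= t_end:
            atp += rng.poisson(r_atp * (t_end - t)) if r_atp > 0 else 0.0
            t = t_end
            record()
            break
        # futile hydrolysis during the holding interval (thinned remainder)
        futile_rate = max(0.0, r_atp - min(motorised, r_atp))
        if futile_rate > 0:
            atp += rng.poisson(futile_rate * dt)
        t += dt
        step = 1 if rng.random() < p_right / prop else -1
        min_before = min(left, right)
        d += step
        if motorised > 0:
            atp += 1.0
            coupled += 1
        record()
        # Arrest is evaluated once per well crossing: on landing in a well
        # other than the one last evaluated, while both flanks satisfy the
        # sensing criterion and the step grew (or kept) the shorter flank.
        # The direction condition means the enzyme only disengages on
        # balance-restoring crossings, so a nucleosome driven in from an
        # end can never settle more than one well beyond the DNA centre.
        # The start well is never crossed into and never arrests.
        if at_well(d) and d != last_well and d != 0:
            last_well = d
            min_after = min(l0 + d, r0 - d)
            if (params.p_arrest > 0
                    and min_after >= params.s_sense
                    and min_after >= min_before
                    and rng.random() < params.p_arrest):
                arrested = True
    else:  # pragma: no cover - safety valve
        raise RuntimeError("event budget exceeded; check rate parameters")

    return Trajectory(np.asarray(times), np.asarray(dyads, float),
                      np.asarray(atps), coupled, arrested, productive)


def simulate(substrate: NucleosomeSubstrate | str, dimer: DimerSpec | str,
             params: SimParams | None = None, t_end: float = 3600.0,
             n_molecules: int = 100, seed: int | None = None) -> TrajectoryEnsemble:
    """Simulate an ensemble of independently sliding nucleosomes.

    ``substrate`` may be an ``aNb`` string and ``dimer`` a species label
    (making a homodimer).  With ``params=None`` the rate parameters are
    resolved from the dimer's domain composition via the packaged presets.
    """
    if isinstance(substrate, str):
        substrate = parse_substrate(substrate)
    if isinstance(dimer, str):
        dimer = make_dimer(dimer)
    if params is None:
        params = params_for_dimer(dimer)
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if seed is None:
        seed = 0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    trajs = tuple(_simulate_one(substrate, dimer, params, float(t_end), rng)
                  for _ in range(n_molecules))
    return TrajectoryEnsemble(substrate, dimer, params, float(t_end),
                              int(seed), trajs)


@dataclass(frozen=True)
class BandPattern:
    """Gel-band ladder: |offset from DNA centre| per band and its occupancy."""

    positions: np.ndarray   # bp from centre (absolute), ascending
    occupancies: np.ndarray # fraction of molecules per reported band
    threshold: float

    @property
    def n_bands(self) -> int:
        return int(self.positions.size)


def band_pattern_from_offsets(offsets: np.ndarray, well_period: int = 10,
                              occupancy_threshold: float = 0.05) -> BandPattern:
    """Bin end-point offsets (bp from DNA centre) into the well-grid ladder."""
    offsets = np.asarray(offsets, float)
    if offsets.size == 0:
        raise ValueError("empty position set")
    binned = np.round(np.abs(offsets) / well_period).astype(int) * well_period
    values, counts = np.unique(binned, return_counts=True)
    occ = counts / offsets.size
    keep = occ >= occupancy_threshold
    return BandPattern(values[keep].astype(float), occ[keep],
                       float(occupancy_threshold))


def band_pattern(ensemble: TrajectoryEnsemble,
                 occupancy_threshold: float = 0.05) -> BandPattern:
    """Reduce end-point dyad positions to a gel-band ladder.

    Positions are binned to the 10 bp well grid by absolute distance from
    the DNA centre (a gel cannot distinguish left from right of centre);
    wells holding at least ``occupancy_threshold`` of the molecules are
    reported as bands.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    return band_pattern_from_offsets(ensemble.offsets_from_centre,
                                     ensemble.params.well_period,
                                     occupancy_threshold)


def fret_proxy(ensemble: TrajectoryEnsemble, labelled_end: str = "left",
               times: np.ndarray | None = None,
               decay_bp: float = 14.0):
    """Map an ensemble to a normalised sliding-FRET trace.

    The donor sits on the ``labelled_end`` of the DNA; per molecule the
    signal decays exponentially (length scale ``decay_bp``) with the
    distance of the octamer edge from that end, i.e. with the flank length
    on the labelled side.  The ensemble mean is normalised to 1 at t = 0.
    """
    from .kinetics import AssayTrace  # local import to avoid a cycle

    if labelled_end not in ("left", "right"):
        raise ValueError("labelled_end must be 'left' or 'right'")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if times is None:
        times = np.linspace(0.0, ensemble.t_end, 241)
    times = np.asarray(times, float)
    half = (ensemble.substrate.footprint - 1) // 2
    sig = np.zeros_like(times)
    for tr in ensemble.trajectories:
        dyad = tr.dyad_at(times)
        if labelled_end == "left":
            flank = dyad - half
        else:
            flank = (ensemble.substrate.dna_length - 1) - dyad - (
                ensemble.substrate.footprint - 1 - half)
        sig += np.exp(-np.maximum(flank, 0.0) / decay_bp)
    sig /= len(ensemble)
    if sig[0] != 0:
        sig = sig / sig[0]
    return AssayTrace(times, sig, kind="sliding_fret",
                      meta={"substrate": ensemble.substrate.name,
                            "labelled_end": labelled_end,
                            "seed": ensemble.seed})


def sensing_range(params: SimParams | None = None, preset: str | None = "WT",
                  grid: Sequence[int] = (20, 30, 40, 50, 60, 70, 80),
                  n_molecules: int = 300, t_end: float = 3600.0,
                  seed: int = 0, threshold_bp: float = 2.0) -> int:
    """Operational flank-sensing limit of a preset, in bp.

    Simulates centred ``xNx`` substrates over a 10 bp grid and returns the
    largest ``x`` at which the ensemble mean absolute dyad displacement
    stays below ``threshold_bp`` — the longest symmetric flank the dimer
    still reads as "too short to slide across".
    """
    if params is None:
        params = SimParams.from_preset(preset or "WT")
    dimer = make_dimer("WT")
    best = 0
    for i, x in enumerate(grid):
        ens = simulate(NucleosomeSubstrate(x, x), dimer, params,
                       t_end=t_end, n_molecules=n_molecules,
                       seed=seed + 7919 * i)
        if ens.mean_abs_displacement() < threshold_bp:
            best = max(best, int(x))
    return best
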