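"""Synthetic assay generators with recorded ground truth.

Each generator emulates one of the study's assay designs — equilibrium
MST binding titrations at 20 nM labelled nucleosome, saturation
titrations at 500 nM, one-pot sliding/ATPase kinetics at 100 nM
nucleosome with 200 µM NADH, and gel-shift band intensities — and
returns the same containers the analysis modules consume, alongside the
generating parameters so recovery tests are automatic.

Noise is multiplicative Gaussian on the signal (2% by default, matching
the scatter of fluorescence-based readouts); concentration grids default
to 16-point two-fold serial dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import Titration
from .kinetics import ADPStandard, AssayTrace
from .presets import activity_preset, binding_preset, stoichiometry_preset
from .simulator import TrajectoryEnsemble, fret_proxy

__all__ = [
    "GeneratorConfig",
    "dilution_grid",
    "gen_binding_titration",
    "gen_stoichiometry_titration",
    "gen_rate_titration",
    "gen_kinetic_traces",
    "gen_emsa",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings: noise model, replication, grid, seed."""

    noise: float = 0.02          # multiplicative Gaussian fraction
    noise_floor: float = 0.0     # additive Gaussian SD, signal units
    replicates: int = 1
    grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0 or self.noise_floor < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.grid is not None:
            g = np.asarray(self.grid, float)
            object.__setattr__(self, "grid", g)
            if np.any(np.diff(g) <= 0):
                raise ValueError("grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xDA7A]))


def dilution_grid(top: float, n: int = 16, factor: float = 2.0) -> np.ndarray:
    """Two-fold (by default) serial dilution series, ascending, ending at ``top``."""
    return top / factor ** np.arange(n - 1, -1, -1, dtype=float)


def _noisy(rng: np.random.Generator, y: np.ndarray,
           config: GeneratorConfig) -> np.ndarray:
    out = y * (1.0 + config.noise * rng.standard_normal(y.shape))
    if config.noise_floor > 0:
        out = out + config.noise_floor * rng.standard_normal(y.shape)
    return out


def _replicated(config: GeneratorConfig, conc: np.ndarray,
                model: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if config.replicates == 1:
        return conc, _noisy(rng, model, config), None
    concs, resps, reps = [], [], []
    for r in range(config.replicates):
        concs.append(conc)
        resps.append(_noisy(rng, model, config))
        reps.append(np.full(conc.size, r))
    return (np.concatenate(concs), np.concatenate(resps),
            np.concatenate(reps))


def gen_binding_titration(config: GeneratorConfig = GeneratorConfig(),
                          preset: str = "CTD_DNA",
                          ligand_conc: float = 20.0,
                          **param_overrides) -> Titration:
    """Equilibrium binding titration from a Hill-model preset.

    The default emulates the MST design: labelled ligand held at a low
    fixed concentration, protein in a 16-point two-fold dilution series
    bracketing K_half.  Ground truth goes in ``meta["truth"]``.
    """
    p = binding_preset(preset)
    p.update(param_overrides)
    conc = config.grid if config.grid is not None else dilution_grid(16.0 * p["K_half"])
    from .binding import hill_response
    model = hill_response(conc, p["K_half"], p["h"], p["F_min"], p["F_max"])
    rng = config.rng()
    c, y, rep = _replicated(config, conc, model, rng)
    return Titration(c, y, ligand_conc=ligand_conc, unit=p.get("unit", "nM"),
                     replicate_id=rep,
                     meta={"truth": p, "preset": preset, "seed": config.seed})


def gen_stoichiometry_titration(config: GeneratorConfig = GeneratorConfig(),
                                preset: str = "WT_500nM",
                                **param_overrides) -> Titration:
    """Saturation titration: linear rise to a breakpoint, then flat.

    The ligand (nucleosome) is held far above K_d, so response is linear
    in protein until every site is filled at ``ratio × ligand_conc``.
    """
    p = stoichiometry_preset(preset)
    p.update(param_overrides)
    ligand = float(p["ligand_conc"])
    breakpoint = p["ratio"] * ligand
    conc = (config.grid if config.grid is not None
            else np.linspace(breakpoint / 8.0, 2.0 * breakpoint, 16))
    s1, s2 = float(p["slope_unsat"]), float(p["slope_sat"])
    plateau = s1 * breakpoint
    model = np.where(conc <= breakpoint, s1 * conc,
                     plateau + s2 * (conc - breakpoint))
    rng = config.rng()
    c, y, rep = _replicated(config, conc, model, rng)
    return Titration(c, y, ligand_conc=ligand, unit=p.get("unit", "nM"),
                     replicate_id=rep,
                     meta={"truth": p, "preset": preset, "seed": config.seed})


def gen_rate_titration(config: GeneratorConfig = GeneratorConfig(),
                       preset: str = "WT_sliding",
                       **param_overrides) -> Titration:
    """Initial-rate titration from an allosteric-sigmoidal activity preset.

    Emulates extracting V_0 at each protein concentration from the one-pot
    sliding/ATPase assay (100 nM nucleosome; saturation near the 2:1
    complex:nucleosome ratio).
    """
    p = activity_preset(preset)
    p.update(param_overrides)
    conc = (config.grid if config.grid is not None
            else 12.5 * 2.0 ** np.arange(7, dtype=float))  # 12.5..800 nM
    from .binding import hill_response
    model = hill_response(conc, p["K_half"], p["h"], 0.0, p["V_max"])
    rng = config.rng()
    c, y, rep = _replicated(config, conc, model, rng)
    return Titration(c, y, ligand_conc=100.0, unit=p.get("unit", "nM"),
                     replicate_id=rep,
                     meta={"truth": p, "preset": preset, "seed": config.seed})


def gen_kinetic_traces(config: GeneratorConfig = GeneratorConfig(), *,
                       tau_s: float = 30.0, plateau: float = 0.03,
                       atp_rate_uM_s: float = 0.4,
                       standard_slope: float = 5.0,
                       nadh_conc: float = 200.0,
                       t_end: float = 300.0, n_samples: int = 301,
                       ensemble: TrajectoryEnsemble | None = None,
                       ) -> dict:
    """Paired sliding (FRET) and ATPase (NADH) traces with known truth.

    With ``ensemble=None`` the sliding trace is a single-exponential decay
    to ``plateau`` with time constant ``tau_s``; when a simulator ensemble
    is supplied its FRET proxy is used instead and the ATP rate is taken
    from the ensemble's ledger.  The NADH trace falls linearly with slope
    ``standard_slope × atp_rate`` so conversion through the matching ADP
    standard round-trips the rate.
    """
    rng = config.rng()
    times = np.linspace(0.0, t_end, n_samples)
    if ensemble is not None:
        sliding = fret_proxy(ensemble, times=times)
        n_uM = 0.1  # 100 nM nucleosome, expressed in µM
        atp_per_mol = np.array([np.mean(ensemble.atp_at(t)) for t in times])
        atp_rate_uM_s = float(
            np.polyfit(times, atp_per_mol, 1)[0] * n_uM)
        s_sig = sliding.signal
    else:
        s_sig = plateau + (1.0 - plateau) * np.exp(-times / tau_s)
    s_sig = _noisy(rng, np.asarray(s_sig, float), config)
    sliding_trace = AssayTrace(times, s_sig, kind="sliding_fret",
                               meta={"seed": config.seed})

    nadh0 = nadh_conc * standard_slope  # FU at t = 0
    n_sig = nadh0 - standard_slope * atp_rate_uM_s * times
    n_sig = _noisy(rng, n_sig, config)
    atpase_trace = AssayTrace(times, n_sig, kind="atpase_nadh",
                              meta={"seed": config.seed})
    return {
        "sliding": sliding_trace,
        "atpase": atpase_trace,
        "standard": ADPStandard(slope=standard_slope, nadh_conc=nadh_conc),
        "truth": {"tau_s": tau_s, "plateau": plateau,
                  "atp_rate_uM_s": atp_rate_uM_s,
                  "standard_slope": standard_slope, "seed": config.seed},
    }


def gen_emsa(config: GeneratorConfig = GeneratorConfig(),
             K_half: float = 1.0, h: float = 1.8,
             dna_conc: float = 0.05, total_intensity: float = 1000.0) -> dict:
    """Gel-shift band intensities vs protein concentration.

    Bound fraction follows the Hill model (defaults match the CTD binding
    a 50 bp duplex at ~1 µM apparent K_d); free and shifted band
    intensities conserve the per-lane total by construction, then receive
    common multiplicative lane noise.
    """
    from .binding import hill_response
    conc = config.grid if config.grid is not None else dilution_grid(16.0 * K_half)
    bound = hill_response(conc, K_half, h, 0.0, 1.0)
    rng = config.rng()
    lane = 1.0 + config.noise * rng.standard_normal(conc.size)
    shifted = total_intensity * bound * lane
    free = total_intensity * (1.0 - bound) * lane
    return {
        "conc": conc, "free": free, "shifted": shifted,
        "bound_fraction": bound,
        "truth": {"K_half": K_half, "h": h, "dna_conc": dna_conc,
                  "total_intensity": total_intensity, "seed": config.seed},
    }
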