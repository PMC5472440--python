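# Methods

This note records the models implemented in `dimerslide`, their
assumptions, the parameter defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Equilibrium binding (module `binding`)

Binding titrations are modelled by the Hill equation
`F(P) = F_min + (F_max − F_min)·P^h/(K½^h + P^h)`.  Fitting is
unweighted least squares (lmfit, `least_squares` with parameter
tolerances ~1e-14) with multi-start initialisation: K½ is seeded at the
concentration where the response crosses its midpoint, h at 1 and at 2,
and the better chi-square wins.  Concentration units are carried
explicitly and never converted; every fit reports in the unit of its
input.  A titration whose response range falls below a relative noise
floor (default 1e-3 of the signal scale) raises `FlatResponseError`
rather than returning a meaningless fit — this is the behaviour wanted
for motor-dead complexes whose activity titrations carry no signal.

The Hill plot (`hill_linearize`) regresses log(θ/(1−θ)) on log P using
fractional saturation computed from the fitted amplitudes.  Points with
θ < 0.1 or θ > 0.9 are excluded: the extremes of the range carry the
largest leverage errors on the logit scale, and 10–90 % is the
conventional linear-region choice.  On noiseless model data the slope
equals the fitted h exactly.

Stoichiometry (`fit_stoichiometry`) assumes a saturation design: ligand
held far above K_d so the response is a rising line that breaks to a
plateau.  The series is split into an unsaturated prefix and saturated
suffix; the split is chosen by minimising the summed squared residuals
of the two straight-line fits over all admissible partitions (each
segment must span at least two distinct concentrations).  The
intersection `(Y₁ − Y₂)/(S₂ − S₁)` divided by the ligand concentration
is the stoichiometry; parallel segments (|S₁ − S₂| below tolerance) are
an error, and a breakpoint outside 0.1–10× the titrated range warns.

## Kinetics (module `kinetics`)

Initial velocities are slopes of a linear regression over an early
window; the default window is the first 10 % of the time to
half-completion, widened when necessary to hold at least four samples.
Sliding FRET traces are normalised to a fixed 100,000 FU full scale
before analysis, with the scale factor stored on the trace.

The NADH-coupled ATPase assay is treated as fast and linear: one ADP
released oxidises one NADH, so ATP turnover is |signal slope| divided by
the ADP standard-curve slope measured at the assay's NADH concentration
(200 µM, or 400 µM for long monitoring).  Per-enzyme rates divide by
enzyme concentration; simulator-derived rates are expressed per
dimer-bound nucleosome.

Rate titrations use the allosteric sigmoidal model — the Hill form with
the baseline fixed at zero, since no enzyme means no activity.  A
straight line through the origin competes with the sigmoid by an
extra-sum-of-squares F-test at α = 0.05, computed on residuals weighted
by the linear prediction (fluorescence noise is multiplicative, so
relative residuals are the homoscedastic scale; an unweighted
comparison lets the sigmoid chase the largest-signal points and
misclassifies genuinely linear series about half the time at typical
designs).  A fitted K½ beyond the top titrated concentration is also
classified linear — no saturation was observed.  This replaces an
information-criterion comparison for the same reason: AICc's penalty is
too weak at 7–13 point designs under heteroscedastic noise.

Coupling efficiency is ATP hydrolysed per base pair slid.  Zero base
pairs with nonzero ATP is reported as a `fully_uncoupled` sentinel, not
a number.

## Sliding simulator (module `simulator`)

Geometry: a 147 bp footprint, 0-based dyad coordinate, flanks named in
`aNb` form (left flank, footprint, right flank).  The flank sum is
invariant; 1 bp is the elementary step, and the 10 bp banding emerges
from the phasing landscape rather than from a 10-bp step size.

Per molecule, a continuous-time Markov chain with three stepping
channels, where σ(l) is a logistic in flank length l with midpoint
`s_sense` and width `sense_width`:

* **drift** — active while the shorter flank is within sensing range
  (≤ `s_sense`): steps that grow the shorter flank at rate
  `k_step0·max(0, σ(l_long) − σ(l_short))`.  Rates are proportionately
  reduced for short flanks and vanish as the flanks balance.
* **blind** — active when both flanks strictly exceed `s_sense`: the
  dimer senses neither end, the two protomers tug in opposition, and
  the nucleosome steps undirected at `k_step0/2` per direction.  This
  channel is what mobilises centred nucleosomes with > 50 bp flanks
  while leaving 50 bp flanks immobile; a drift-only law would freeze
  every symmetric substrate and misreport the operational sensing
  limit.
* **leak** — optional undirected stepping at `k_leak` when both motor
  channels are silent; 0 in the shipped presets, exposed because
  sub-well oscillations of arrested nucleosomes cannot be excluded.

Arrest: wells sit every `well_period` = 10 bp in register with the
start position (the strong-positioning sequence is idealised as a
periodic landscape; the real sequence is not modelled).  When a step
crosses into a new well while both flanks satisfy the sensing
criterion *and* the step grew the shorter flank, the molecule arrests
with probability `p_arrest`.  The direction condition makes the stop
progressive and balance-seeking: a nucleosome driven in from an end can
settle at most one well beyond the DNA centre, which is also enforced
as a property test.  The start well is never crossed into and never
arrests.  An arrest criterion based on near-saturation of the sensing
function (σ ≥ 0.95) was considered and rejected: with an 8 bp logistic
it requires ~74 bp flanks, unreachable on the 140 bp flank budget where
the three-band ladder is observed, so it cannot produce the laddered
products at all.

ATP ledger: each active motor hydrolyses at `k_atp` while bound,
independent of stepping.  Motor-driven steps debit the same ledger —
implemented by splitting the ATP Poisson process into step events and
futile events at rate `max(0, n_motors·k_atp − step propensity)` — so
`atp_count ≥ coupled steps` holds for every molecule by construction,
and hydrolysis continues at an unchanged bulk rate after sliding
completes.

Heterodimers: a dimer with exactly one active motor is productive in
exactly one of its two binding orientations; the orientation is drawn
uniformly per molecule unless forced.  Dimers with no active motor
produce no steps and no ATP.

### Parameter defaults and calibration

| parameter | WT | ΔCTD | unit | rationale |
|---|---|---|---|---|
| `k_step0` | 1.0 | 0.2 | bp/s | WT: a 0N100 nucleosome is > 90 % repositioned by 90 s and finished well before 200 s; ΔCTD: five-fold lower maximal sliding |
| `s_sense` | 50 | 30 | bp | operational sensing limits: 50 bp for the full complex, strictly under 40 bp for the CTD deletion (30 is the largest 10-bp grid value satisfying the bound under the simulator's own limit detector) |
| `sense_width` | 8 | 8 | bp | soft sensing: initial rate grows smoothly with overhang length and saturates above ~50 bp |
| `k_atp` | 20/9 ≈ 2.22 | 40/9 | s⁻¹ per motor | a WT dimer then consumes 2·(20/9)·90 = 400 ATP in the first 90 s of a 0N100 run, 8 per bp of the 50 bp slid; ΔCTD doubles turnover.  This sits just above the 1–2 s⁻¹ per-motor band quoted for the enzyme; the completion and ATP-per-bp constraints were given priority |
| `p_arrest` | 0.2 | 0.2 | – | calibrated so a 0N140 start yields exactly three occupied wells (centred, 10, 20 bp) with the centred product well populated |
| `well_period` | 10 | 10 | bp | helical-turn phasing of the positioning sequence |
| `k_leak` | 0 | 0 | bp/s | undirected blind-zone stepping already accounts for off-centre sliding of 50N50 by the CTD deletion; a nonzero leak would mobilise every substrate over long runs and destroy the sensing-limit readout |

Dimers lacking both CTDs use the ΔCTD row; one CTD is treated as
sufficient (the domain acts in trans).  The CTD deletion's binding
cooperativity loss (h → 1) lives in the titration presets, not the
stepping law.

## Mixtures (module `mixtures`)

Random pairing of protomer species (no homo/hetero preference, as
supported by indistinguishable binding of the species): p(i,j) = 2fᵢfⱼ,
p(i,i) = fᵢ².  Default activity rules are derived from species
attributes: sliding 0/0.5/1 for 0/1/2 active motors, ATPase m/2 for m
active motors, and a multiplicative ΔCTD factor (×0.2 sliding, ×2
ATPase) when neither protomer has a CTD.  The 0.5 heterodimer value
encodes the orientation hypothesis — half of bindings productive at
full rate.  The alternative reading (every heterodimer at half rate)
is exposed as `heterodimer_mode="uniform"`; the two are
indistinguishable in expectation, which is precisely why the ensemble
data cannot separate them.  `mixture_titration` composes dimer
occupancy (cooperative binding curve) with the Punnett expectation to
emit rate titrations on the same axes the rate fitter consumes.

## Synthetic data (module `synth`)

Generators emulate the study designs: 16-point two-fold dilution MST
titrations (20 nM labelled nucleosome; CTD–DNA truth K½ = 1.0 µM,
h = 1.8), saturation titrations at 500 nM nucleosome with a linear rise
breaking to a plateau at stoichiometry × 500 nM, paired sliding/ATPase
traces (closed-form exponential or simulator-sourced, with the NADH
slope encoding a known ATP rate through a synthetic ADP standard), and
gel-shift lanes conserving per-lane intensity.  Noise is multiplicative
Gaussian at 2 % by default — appropriate for fluorescence readouts and
matching the visual scatter of such data — with an optional additive
floor.  Every generator records its ground truth and seed in the
output's metadata.

What the generators do *not* emulate: thermophoresis physics and raw
MST traces, fluorophore photophysics, pipetting/series correlations,
baseline drift, and enzyme exchange between nucleosomes during a
reaction.  Passing recovery tests therefore demonstrate that the
analysis stack is correct and well-calibrated for idealised assays of
the published design, not that it is robust to every artefact of real
instruments.

## Numerical and interface choices

Tables are UTF-8 delimited text with a required header; units ride in
column names (`conc_nM`, `time_s`) and metadata (including seeds) in
leading `#key=value` lines.  Decimal-comma files are rejected with an
explicit message rather than silently misparsed.  All stochastic
entry points take integer seeds; fixed seed means bit-identical output.
Problem sizes in the shipped analyses (300–1000 molecules, 200–7200 s
horizons, 3–20 replicates) were chosen so each desk-scale check
resolves its target comfortably within statistical tolerance.

## Known limitations

* The functional form of the flank-sensing rate law is not measured;
  the logistic drift/blind-zone decomposition is one consistent choice
  that reproduces the end-point phenomenology (centring, ladders,
  sensing limits) and is flagged as a model assumption.
* Arrest is phenomenological; no microscopic model of engagement with
  the phased wells is attempted, and the real positioning-sequence
  energetics are idealised as a uniform 10 bp grid.
* Post-completion ATPase is treated as constant; any rate increase
  after sliding stops is not modelled.
* Protomer exchange between dimers, multi-nucleosome arrays and
  histone-tail regulation are out of scope.
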