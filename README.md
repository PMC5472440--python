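# dimerslide

Quantitative models for nucleosome sliding by a **dimeric chromatin
remodeller** (the human INO80 complex): cooperative binding analysis,
sliding/ATPase kinetics, a Punnett-square model for mixed-dimer
populations, and a stochastic simulator of flank-length-sensing
nucleosome repositioning.

## The science

INO80 binds nucleosomes as a dimer of two large complexes and slides
them away from DNA ends.  Several quantitative signatures follow from
the dimeric mechanism, and this package implements each of them as
testable code:

* **Cooperative binding and activity.**  Binding of the complex to
  nucleosomes, and the dependence of sliding rate on enzyme
  concentration, follow the Hill model

      F(P) = F_min + (F_max − F_min) · Pʰ / (K₁/₂ʰ + Pʰ)

  with h ≈ 2 for binding and sliding (two complexes act together) but a
  weaker h ≈ 1.3 for ATP hydrolysis (one motor suffices to hydrolyse).
  `fit_hill` / `fit_rate_titration` estimate (K₁/₂, h) by least squares;
  `hill_linearize` confirms h from the slope of log(θ/(1−θ)) vs log P
  with the conventional 10–90 % saturation retention band.

* **Stoichiometry by breakpoint.**  Titrating enzyme into nucleosomes
  held far above K_d gives a response that rises linearly and then
  plateaus; the two fitted lines intersect at
  (Y₁ − Y₂)/(S₂ − S₁), and dividing by the nucleosome concentration [N]
  gives the number of complexes bound — two per nucleosome
  (`fit_stoichiometry`).

* **Punnett mixtures.**  Co-assembling wild-type protomers with
  motor-dead (Walker-mutant, "EA") protomers at 1:1 yields
  WT:WT / WT:EA / EA:EA dimers at 1:2:1 by random pairing.  A single
  motor is sufficient to slide, but only in one of the dimer's two
  binding orientations, so the ensemble sliding rate of the 1:1 mixture
  is 50 % of pure wild type (`dimer_distribution`, `predict_activity`).

* **Flank sensing and the sliding end point.**  The dimer senses
  flanking DNA out to ~50 bp on either side.  The simulator
  (`simulate`) is a continuous-time Markov chain over 1-bp steps:
  directional stepping grows the shorter flank at a rate set by a soft
  (logistic) sensing function, undirected stepping takes over when
  both flanks exceed the sensing range, and molecules settle into
  10-bp phased wells with a fixed arrest probability per crossing.
  Each active motor hydrolyses ATP continuously (~2 s⁻¹) whether or not
  it steps, reproducing the observed excess of ~8 ATP per base pair
  slid and the ATPase activity that continues after sliding completes.

## Worked example

Generate a synthetic binding titration of the Ino80 C-terminal domain
against a 50 bp duplex (16-point two-fold dilution, 20 replicates, 2 %
noise), fit it, and run the main simulator analyses:

```
$ dimerslide generate --assay binding --noise 0.02 --replicates 20 --seed 21 --out ctd.csv
$ dimerslide fit-binding ctd.csv
K_half=1.003130794569629
h=1.7967040001410877
...
hill_plot_slope=1.7633831395496449
```

The fitted half-saturation point (1.00 µM) and Hill coefficient (1.80,
confirmed at 1.76 by the Hill-plot slope) recover the cooperative
DNA-binding behaviour of the domain.

```
$ dimerslide bands --substrate 0N140 --preset WT --n 500 --seed 3
n_bands=3
positions_bp_from_centre=0,10,20
occupancies=0.310,0.454,0.236
```

An end-positioned nucleosome with a 140 bp overhang is repositioned into
a three-band ladder — centred, 10 bp and 20 bp from centre — because
molecules arrest stochastically in successive 10-bp wells once both
flanks exceed the sensing range.

```
$ dimerslide mixture --mix WT=0.5,EA=0.5
p[EA:EA]=0.2500
p[EA:WT]=0.5000
p[WT:WT]=0.2500
relative_sliding=0.5

$ dimerslide sensing-range --preset WT --seed 11
sensing_limit_bp=50
```

The equimolar wild-type/motor-dead mixture forms dimers at 1:2:1 and
slides at half the wild-type rate; centred nucleosomes remain immobile
up to symmetric 50 bp flanks and are mobilised beyond.

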