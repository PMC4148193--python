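# insulator-bridge

Quantitative analyses of how chromatin-insulator proteins bind DNA and
bridge long-range DNA interactions (LRIs), for biophysicists and
genomicists working on genome organization.  In the *Drosophila*
insulator system, a DNA-specific factor (BEAF32) binds clustered CGATA
motifs cooperatively, while associated factors (CP190, Chromator)
provide the protein–protein contacts that join two protein-bound DNA
molecules into one complex.  This package implements the three analysis
stages by which that picture is established quantitatively, each
exercisable end-to-end on synthetic data:

1. **Binding isotherms** (`insulator_bridge.binding`) — fluorescence
   anisotropy titrations fitted with single-site (Langmuir,
   `f = [P]/(K_D+[P])`) or Hill (`f = [P]^n/(K_D^n+[P]^n)`) models, and
   competition titrations (hyperbolic decay → EC50 → Cheng–Prusoff
   `K_i`).
2. **FCS/FCCS** (`insulator_bridge.correlation`) — one-component 3-D
   diffusion + triplet autocorrelation fits,
   `G(τ) = (1/N)[1 + T/(1−T)e^(−τ/τ_T)](1+τ/τ_D)^(−1)(1+τ/(s²τ_D))^(−1/2)`,
   cross-correlation fits, and the bridged-fraction estimator
   `f = A/(p_hetero · e_g · e_r)` that corrects the relative
   cross-correlation amplitude `A` for the two-color pairing ceiling
   (at most `2q(1−q) = 50 %` of bridged pairs are two-colored) and for
   incomplete labeling.
3. **Hi-C aggregation** (`insulator_bridge.hic`) — anchor→target pile-up
   profiles (500 bp offset bins, ±5 kb around targets at 15–60 kb from
   anchors, normalized by candidate-site counts, feature-free control,
   Wilcoxon rank-sum significance) and peak-overlap/Venn statistics.

`insulator_bridge.simulate` provides seeded generators for every stage:
noisy titrations, Brownian-dynamics two-color photon traces through a
3-D Gaussian confocal volume with a tunable bridged fraction, a
multi-tau correlator, and distance-decaying contact maps with localized
enrichment.  `insulator_bridge.io` reads/writes BED, GFF3, and the TSV/
JSON formats; a thin CLI (`insulator-bridge`) wraps the main pipelines.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Fitting synthetic titrations of a motif-bearing vs a scrambled DNA probe
(`examples/fit_binding_isotherm.py`):

```
DNA with binding motifs:
  K_D =   72.0 +/- 4.5 nM   Hill n = 2.39 +/- 0.34   delta_r = 33.1 units
scrambled DNA:
  K_D =  159.6 +/- 52.1 nM   Hill n = 1.80 +/- 0.94   delta_r = 10.3 units
```

The motif-bearing probe fits with a Hill coefficient well above 1 —
cooperative, multimeric binding — while the scrambled probe's
coefficient is consistent with 1 within its standard error
(non-cooperative binding); single noisy titrations scatter around the
generating values (K_D 68/165 nM, n 3/1).

Estimating a bridged fraction from a simulated dual-color measurement
(`examples/fccs_bridging.py`):

```python
import insulator_bridge as ib

cfg = ib.FccsSimConfig(seed=1, n_molecules=200, bridged_fraction=0.65,
                       duration=20.0)
trace = ib.simulate_intensity_traces(cfg)
auto_green = ib.correlate_traces(trace.green, trace.green, dt=cfg.dt,
                                 channel_pair="green_auto")
cross = ib.correlate_traces(trace.green, trace.red, dt=cfg.dt,
                            channel_pair="cross")
A = ib.relative_cc_amplitude(cross, auto_green)
f = ib.bridged_fraction(A).bridged_fraction
```

prints

```
relative cross-correlation amplitude A = 0.183
estimated bridged fraction            f = 0.66
```

With 65 % of the DNA molecules bridged into pairs, the measured relative
cross-correlation amplitude is only ~0.18: same-color pairs are
invisible to the cross-correlation and dark (unlabeled) molecules dilute
it further.  The estimator divides those factors back out (an amplitude
of 0.18 corresponds to a bridged fraction of 65 %; 0.13 to 47 %).

Recovering a 3× contact enrichment from a synthetic contact map
(`examples/hic_aggregation.py`):

```
1282 anchor/target pairs at 15-60 kb (7268 control pairs)
central signal = 0.435, control = 0.157, ratio = 2.77
Wilcoxon two-sided p = 3.07e-65
```

The aggregation profile is flat at the distance-decay background except
at offset 0 — the co-bound target bin itself — where contacts with the
anchor are ~3-fold enriched, matching the simulated enrichment.

Other examples: `examples/competition_ki.py` (EC50 → K_i).

## Command line

```sh
insulator-bridge fit-isotherm --model hill --in iso.tsv --out fit.json
insulator-bridge bridge-fraction --a 0.18 --eff-green 0.57 --eff-red 0.97   # prints 0.651
insulator-bridge simulate-hic --seed 3 --out-prefix sim
insulator-bridge hic-aggregate --anchors sim.beaf32.bed \
    --targets sim.cp190.bed,sim.chromator.bed --contacts sim.contacts.tsv \
    --out profile.tsv
insulator-bridge overlap-venn a.bed b.bed c.bed
```

Every subcommand writes a JSON run manifest (inputs, parameters, seed,
version) next to its outputs; diagnostics go to stderr, machine output
to files.

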