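# clmscreen

Pooled ("combinatorial library") screening of microbial biocatalysts:
design of pooled incubation batches, simulation of whole-cell
ketone-reduction / alcohol-oxidation readouts, group-testing deconvolution
of active strains, and the redox-kinetics and enantiomer algebra needed to
recognize tandem stereoinversion chemistry hiding inside a pool.

## Who this is for

Biocatalysis groups screen strain collections for useful redox activity —
typically the enantioselective reduction of a ketone to a chiral alcohol.
Testing every strain against every substrate is slow: `n_strains x
n_substrates` incubations plus as many chromatographic analyses. Pooling
cuts this dramatically: strains are distributed across a few batches, each
batch is incubated once per substrate mixture, and each strain's
batch-membership *signature* lets the batch-level results be decoded back to
individual strains. A 12-strain library in 4 batches needs 4 pooled
incubations instead of 12; with two individual confirmations the total is 6.
A 24-strain library against 5 substrates costs 120 conventional assays; the
simulated end-to-end study here resolves it in 16.

The same pooled read-through can *surprise*: if one strain reduces a ketone
and a batch-mate oxidizes the (S)-alcohol back, the product appears early
and then vanishes, and the residual alcohol drifts toward (R). `clmscreen`
treats these violations of the pooling logic as first-class signals — it
flags them, names the strains best placed to explain them, and provides the
kinetic and stereochemical tools to confirm the mechanism.

## The core model

Amounts are normalized fractions (K + R + S = 1) and every step is first
order:

    K  --kR-->  R        K  --kS-->  S
    R  --phi*koxR-->  K  (usually koxR = 0)
    S  --phi*koxS-->  K

with `phi` in [0, 1] the oxygen-availability factor (0 = anaerobic; the
oxidase is oxygen dependent) and, in dense suspensions, `phi = h/(h +
biomass)` — respiration competes with the oxidase for oxygen. Three exact
consequences drive the analysis:

- anaerobic alcohol ee = `(kR - kS)/(kR + kS)` at every time point;
- with `koxS > 0, koxR = 0, kR > 0`, racemic alcohol is driven entirely to
  (R) (complete deracemization);
- **oxidation-only bound**: without reduction, the (R)-alcohol yield from a
  starting ee of `ee0` can never exceed `(1 + ee0)/2` — 50 % from a
  racemate. Observing more (R) than that *proves* re-reduction, i.e. a
  tandem oxidation/reduction rather than a simple kinetic resolution.

Decoding uses the group-testing union model (a batch is a hit iff it holds
an active strain); candidates are all strain sets up to a chosen size whose
signature union equals the hit set, checked exhaustively.

## Worked example

The bound argument on printed assay numbers — racemic phenylethanol
incubated with an oxidizing yeast leaves 85 % alcohol at 83 % (R)-ee:

```
$ clm stereo split --alcohol 0.85 --ee 0.83
{
  "R_fraction": 0.77775,
  "S_fraction": 0.07225000000000001,
  "margin": 0.27775000000000005,
  "oxidation_only_bound": 0.5,
  "reduction_inferred": true
}
```

The (R)-alcohol fraction (77.8 % of the starting material) exceeds the 50 %
that S-selective *oxidation alone* could leave from a racemate by a 27.8
point margin: the strain must also be re-reducing the ketone it makes.

An anaerobic reduction with a 4:1 (S)-selective rate ratio (kR = 0.1,
kS = 0.4 /h) shows the closed-form, time-independent ee:

```
$ clm kinetics simulate --k-red-r 0.1 --k-red-s 0.4 --oxygen-factor 0 --times 0,4,24
t_h,K,R,S,ee,conversion
0.0,1.000000,0.000000,0.000000,nan,0.000000
4.0,0.135335,0.172933,0.691732,-0.600000,0.864665
24.0,0.000006,0.199999,0.799995,-0.600000,0.999994
```

The alcohol ee is -0.60 ((S)-excess) at 4 h and 24 h alike — anaerobic ee
is set by the rate ratio, not by time.

The full simulated study (two 12-strain libraries in batches A-D and E-H,
three ketone mixtures, 4 h and 24 h sampling, 3 % measurement noise):

```
$ clm run --seed 1
```

prints a JSON report whose accounting block reads

```
"assay_accounting": {"pooled_assays": 12, "confirmatory_assays": 4,
                     "total": 16, "conventional": 120}
```

— 3 mixtures x 4 batches plus 4 individual confirmations, against 120
one-strain-one-substrate assays. Inside the report, the 2-octanone channel
scores `{"A": 14.0, "B": 13.9, "C": 20.4, "D": 88.3}` (percent conversion
at 24 h) decode to the unique batch-D-exclusive strain `s01`; the
acetophenone channel's product collapses between 4 h and 24 h in batches E
and F, raising `non_monotone_product` flags whose suspicion channel names
`["s14", "s15"]` — and the follow-up incubation of racemic alcohol with
`s15` returns `R_fraction_pct: 61.3` against the 50 % bound, inferring the
tandem mechanism (and nothing happens anaerobically, implicating an
oxidase).

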