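# Methods

## Problem

A library of microorganisms is screened for whole-cell redox activity toward
a panel of ketones. Conventional screening incubates every strain with every
substrate (`n_strains x n_substrates` assays). Pooled screening instead
distributes the strains over a small number of incubation batches — each
strain's batch-membership pattern is its *signature* — incubates each batch
once per substrate mixture, and decodes the batch-level results back to
individual strains. `clmscreen` implements the whole loop: design, forward
simulation of the chemistry, deconvolution, and the kinetic/stereochemical
reasoning needed when the chemistry refuses to obey the decoding model.

## Pooling designs and decoding (design, decode)

A design is a binary strain x batch incidence matrix with every batch
holding exactly `pool_size` strains. Construction distributes each strain's
replication quota (floor/ceil of `slots / n_strains`; for 12 strains in 4
batches of 5, eight strains appear twice and four once) to the batches with
most free slots, with seeded random tie-breaking; distinct signatures are
requested per construction attempt and the attempt loop is bounded.
Infeasibility — too few slots, or a replication profile that admits fewer
distinct signatures than strains — raises a capacity error rather than
silently relaxing a constraint. Notably, the 12-strain/4-batch/pool-5
configuration *cannot* have all-distinct signatures (eight strains need
two-batch signatures but only C(4,2) = 6 exist), so collisions such as two
strains sharing {A, D} are a structural feature of that design, not a bug;
`validate_design` reports collision groups and checks d-separability by
exhaustive subset enumeration, which is exact and cheap at these sizes.

Decoding assumes the union model: a batch is a hit iff it contains at least
one active strain, called by an absolute conversion threshold (default 0.5
at 24 h — the source study compared batches qualitatively, so the cutoff is
this package's choice). `candidates` enumerates all strain sets up to
`max_actives` (default 1, the usual operating assumption; exhaustive up to
3) whose signature union equals the hit set, minimal sets first.

The union model fails, by design, for product-destroying (tandem) activity,
so two anomaly screens run alongside: a *non-monotone product* flag when the
product fraction drops between sampling times by more than 0.10 (absolute),
and a *control/assay divergence* flag when a mixture assay departs from its
single-ketone control by more than 0.20. Flagged batches feed a suspicion
channel (`suspect_strains`, preferring strains whose signature is exactly
the flagged set) that is deliberately kept separate from hit-based
candidates: a batch can be excluded as a reducer and still harbor the
oxidizer, and the decoder does not attempt to reconcile the two.

Margins: with the generator's default 3 % multiplicative measurement noise,
a 0.10 absolute drop on a conversion near saturation is a ~2.6 sigma event
per series, so isolated false flags are possible in large noisy sweeps; the
specificity guarantee (zero false flags) is exact only for noise-free
readouts, where the monotonicity result below applies.

## Redox kinetics (kinetics)

The chemistry is a closed three-species system — ketone K, (R)-alcohol R,
(S)-alcohol S, amounts normalized so K + R + S = 1 — with first-order steps:

    dK/dt = -(kR + kS) K + phi (koxS S + koxR R)
    dR/dt =  kR K - phi koxR R
    dS/dt =  kS K - phi koxS S

`kR`/`kS` are the reduction rates into each alcohol enantiomer, `koxS`/
`koxR` the oxidation rates (koxR defaults to 0: strictly (S)-selective
oxidation), and `phi` in [0, 1] multiplies the oxidation rates to encode
oxygen availability — phi = 0 is strict anaerobiosis, under which an
oxidase-driven oxidation is exactly silent. Two parallel reduction channels
deliberately cover both one poorly selective dehydrogenase and two
dehydrogenases of opposite enantiotoposelectivity; the kinetics cannot
distinguish them. Enzyme saturation is ignored (substrate loads of ~1-2 g/L
keep the first-order regime plausible) and cofactor balance and dissolved
oxygen transport are out of scope.

Because the system is linear with constant coefficients, trajectories are
computed with the matrix exponential of the 3x3 generator — exact to
rounding, and mass-conserving by construction since the generator's columns
sum to zero. An adaptive-integrator cross-check lives in the tests.

Consequences used throughout:

- **Anaerobic ee closed form.** With phi = 0 and a pure-ketone start, the
  alcohol ee equals `(kR - kS) / (kR + kS)` at *every* time point; an
  (S)-excess of 0.60 implies kS/kR = 4. This is why anaerobic incubations
  report a time-stable, modest ee: it is the intrinsic selectivity of the
  reduction alone. (A concentration-dependent anaerobic ee, as measurements
  sometimes show, is outside what a first-order model can produce; noted,
  not modelled.)
- **Complete deracemization limit.** With koxS > 0, koxR = 0 and any
  kR > 0, the (R)-alcohol is the only absorbing species: racemic alcohol is
  driven entirely to (R) as t grows.
- **Monotonicity.** The generator is that of a reversible (tree) Markov
  chain, so from a pure-ketone start K(t) is completely monotone and the
  alcohol fraction 1 - K(t) never decreases. A falling product curve is
  therefore *impossible* under time-invariant rates — which is exactly what
  makes it a reliable anomaly fingerprint (see the generator below).

Oxygen competition with respiration is modelled as a static hyperbolic
factor `phi = h / (h + biomass)` (`oxygen_factor_from_biomass`): 1 at zero
biomass, 0.5 at the half-saturation density h, strictly decreasing. Only
the direction of the biomass effect is empirically constrained; the
hyperbola is this package's choice of the simplest saturating form. Under
it, the final (R)-ee of a deracemization is non-increasing in biomass.

`fit_redox_params` recovers the four rates from observed time courses by
bounded least squares (scipy, non-negativity bounds, residuals over all
species and time points), simulating each observation under its known phi.
Identifiability of the oxidation rates requires at least one aerobic
observation; with anaerobic-only data the fit proceeds but is flagged, and
a numerical rank check of the residual Jacobian (singular values below
1e-7 of the largest) flags flat directions generally. On the simulation
conditions used in the acceptance study (true rates 0.25/0.10/0.30/0.08
h^-1, one aerobic plus one anaerobic course, 8 points over 0.5-24 h, 5 %
multiplicative noise, 50 replicates) the median relative error per rate is
well under 15 %.

## Stereochemistry algebra (stereochem)

Signed ee with (R) positive: `ee = (R - S) / (R + S)`, undefined (nan
sentinel) without alcohol. `split_from_ee` inverts it; all quantities are
molar fractions of initial substrate (reported percentages are treated as
molar; no density/molecular-weight corrections).

The load-bearing result is the **oxidation-only bound**: if the only
available reaction consumes alcohol, the (R)-pool can never grow, so its
yield is capped at its initial fraction `(1 + ee0) / 2` — 50 % from a
racemate. `infer_reduction_present` applies the bound conservatively
(strict inequality; equality does not prove anything), so an observation
like 15 % ketone with 83 % (R)-ee residual alcohol from a racemate
(R-fraction 0.778) forces the conclusion that the intermediate ketone was
re-reduced: a tandem oxidation/reduction, not a simple kinetic resolution.
Whether koxR is exactly zero or merely small cannot be decided from a
single high-but-imperfect ee; the bound argument does not need it.

`kinetic_resolution_E` implements the standard irreversible-resolution
relation `E = ln[(1-c)(1-ee_s)] / ln[(1-c)(1+ee_s)]`; it is exact for two
competing irreversible first-order consumptions (cross-checked against an
ODE oracle to 1 %) and only an effective estimate once back-reaction is
active. Perfect resolutions return a capped sentinel (1e6).

## Synthetic data generator (synthetic_data)

Strains act as parallel first-order catalysts, so a pool's effective rate
for each step is the sum of its members' rates (each strain contributes its
own cells at full density; suspension volumes scale with the number of
batches joined). A noiseless pool whose only active member is s is
therefore identical to s's control — the concordance the screening logic
relies on. Substrates in a mixture transform independently, except for an
optional per-(batch, substrate) cross-inhibition factor scaling reduction
rates in mixture assays only. Measurement noise is multiplicative Gaussian
on conversion (sd 0.03 by default; no error model is available from
measurements, so this is a modelling choice), clipped to [0, 1]; ee is
reported noise-free.

One extension beyond the constant-coefficient core: a strain's reduction
rates may decay exponentially in time (`reduction_decay`, h^-1), emulating
resting cells exhausting their reducing equivalents while an oxygen-driven
oxidase keeps running. By the monotonicity result this is *necessary*: no
constant-rate parameterization can make the product fraction fall between
4 h and 24 h, yet that falling curve is the empirically central tandem
signature. With all decays zero the exact matrix-exponential path is used;
otherwise LSODA with rtol 1e-9 / atol 1e-12.

`make_study_fixture` reconstructs the full two-library scenario: CLM-1
(batches A-D) tested on 2-octanone + acetonaphthone and on 3-octanone +
propiophenone, CLM-2 (batches E-H) on 3-octanone + acetophenone; 24 strains,
pool size 5, eight strains per library in two batches. The incidence
matrices are a **synthetic reconstruction** (the published composition table
is not available in extracted form) constrained by every documented
signature: the fast aliphatic reducer exclusive to D, two aromatic reducers
sharing {A, D}, the suspected oxidizer exclusive to B, the fast 3-octanone
reducer exclusive to E (>= 85 % in 4 h), and the two acetophenone
transformers sharing {E, F}. Ground-truth rate constants were chosen once so
the noiseless readouts land in the documented qualitative bands (e.g. the
E/F phenylethanol fraction ~0.70 at 4 h falling to ~0.3 at 24 h with the ee
flipping from (S)-rich to (R)-rich; batch-B 3-octanone control ~0.9 vs
mixture assay ~0.5). The rival explanations of the weak batch-B aromatic
chemistry are exposed as alternative fixture configurations
(`batch_b_mechanism="oxidation" | "inhibition"`); the fixture asserts
neither.

What the generator does *not* emulate: growth phases, substrate toxicity,
cofactor stoichiometry, metabolite-level inhibition mechanisms, GC
measurement artifacts, and concentration-dependent selectivity. Passing
tests therefore demonstrate the correctness of the design/decode/kinetics
machinery under the stated model, not the behavior of any real strain.

## Reporting conventions (io, cli)

Fractions internally, percentages only at the reporting edge. CSV is
comma-separated UTF-8 with a header; design matrices are strain x batch 0/1
tables; readouts are tidy with columns
`batch_or_strain, substrate, time_h, conversion, alcohol_ee, aeration, mode`.
Schema violations are rejected with 1-based line numbers. `run_study` is
fully deterministic under its seed (per-incubation noise streams are spawned
from one seeded generator) and its JSON report embeds the seed and a digest
of the analysis-relevant configuration.

## Problem sizes

Default suites use the 24-strain/8-batch fixture, 100-seed design sweeps,
200-seed specificity and completeness sweeps, 30 sampled designs (up to 16
strains x 6 batches) for decoder/brute-force equivalence, and 50 replicate
fits for parameter recovery — sizes chosen to exercise every code path while
keeping the whole suite interactive (tens of seconds).
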