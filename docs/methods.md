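# Model and methods

## Scope and state

`nfkbdyn` models bulk-cell NF-κB dynamics as deterministic mass-action
ODEs in two well-mixed compartments (cytoplasm, nucleus). The state tracks
38 species: the monomers RelA, RelB, p50, p100 and p52; the four
transcription-competent heterodimers A50 = RelA:p50, A52 = RelA:p52,
B50 = RelB:p50 and B52 = RelB:p52 in both compartments; free IκBα/β/ε in
both compartments; the cytoplasmic inhibitor–dimer complexes (IκBα with all
four dimers, IκBβ/ε with the RelA dimers only), the transient nuclear
IκBα:dimer complexes that carry export, the p100 sequestration complexes
p100:A50, p100:B50 and p100:B52; and the four NF-κB-inducible mRNAs
(IκBα, IκBε, *Nfkb2*/p100, *Relb*). Units are nM and hours. The derived
readouts are NF-κBn = nA50 + nA52 + nB50 + nB52, nRelA = nA50 + nA52 and
nRelB = nB50 + nB52.

IKK2 activity is a *prescribed input* IKK2(t): the model contains no
receptor or kinase-regulation layer (no A20 feedback onto IKK, no
NIK/IKK1-driven non-canonical processing). Every IKK2-modulated reaction is
the degradation of a classical IκB, free or inside a complex; p100 is never
an IKK2 target — chronic canonical stimulation does not deplete it.

## Reaction structure

- **Synthesis.** RelA, p50 and IκBβ are produced at constitutive
  zeroth-order rates. IκBα, IκBε, p100 and RelB are produced through
  explicit mRNAs whose transcription is `basal + Σ_d w_(gene,d) · [nuclear
  dimer d]` — linear induced transcription, no saturation. *Relb*
  transcription receives weights from all four dimers (RelA-dimer weights
  dominant, RelB-dimer weights small but strictly positive), which closes
  the RelB autoregulatory loop.
- **Dimerisation** of RelA/RelB with p50/p52 is reversible and
  cytoplasmic; free RelB is short-lived unless stabilised in a dimer.
- **Sequestration.** IκBα/β/ε bind RelA dimers tightly; IκBα binds RelB
  dimers only token-weakly (the "less-preferred" interaction). p100 binds
  B50/B52 tightly and A50 weakly, at the dimer level.
- **Transport.** Free dimers import into the nucleus; free IκBs import;
  nuclear IκBα binds nuclear dimers and the complex is exported. Fluxes are
  scaled by the cytoplasm:nucleus volume ratio k_v = 3.3 so molecule
  numbers, not concentrations, are conserved.
- **Degradation.** Free species and mRNAs turn over constitutively;
  inhibitor inside a complex degrades slowly, releasing the intact dimer;
  whole-complex degradation is excluded. IKK2 multiplies the fast
  degradation of cytoplasmic IκBs (free and complexed, the latter
  releasing the dimer).
- **Processing.** Free p100 converts to p52 at a basal first-order rate;
  the p52-processing knockout zeroes exactly this step, leaving p100
  expression intact.

Genotypes are parameter interventions: knockouts zero synthesis (or
processing) rate constants, transcription-source ablations zero individual
*Relb* induction weights; species stay in the state vector and relax to ~0.
"NF-κB-deficient" is represented as the Rela/Relb double null (cRel is not
modelled).

## Numerics

Stiff integration uses LSODA with analytic Jacobian (rtol 1e-8, atol
1e-10 nM), output on a grid of 0.01 h near stimulation onsets and 0.05 h
elsewhere. Pre-equilibration integrates 500 h at basal IKK2 and polishes
with damped Newton iterations projected onto the nonnegative orthant
(plain root-finding can wander to negative-concentration fixed points of
mass-action systems); the accepted state satisfies max |dx/dt| < 1e-8
nM/h. Monte Carlo sensitivity draws reuse the nominal steady state as a
Newton seed and integrate at relaxed tolerance (rtol 1e-6) on a coarser
grid — the late-window AUC ranking is insensitive to this (grid-refinement
invariance is tested).

Duration metrics locate threshold crossings by linear interpolation
between samples; excursions shorter than 0.01 h are treated as grazing
contacts and dropped. In biphasic curves the threshold uses the global
peak. Basal values for basal correction are each genotype's own
pre-stimulus steady state.

## IKK2 inputs

The experimentally measured kinase curves behind the brief (TNFp, 0.5 h
treatment), chronic (TNFc) and IL-1β regimes are not available; the
package emulates their qualitative features with piecewise-exponential
profiles whose constants are fixed in `nfkbdyn.ikk.PROFILE_CONSTANTS`:
basal 0.2 nM; TNFp peaks at 60 nM by 0.2 h and falls with τ = 0.26 h
(within 5% of the basal-corrected peak by 1 h, above-threshold width
< 1 h); TNFc shares the early peak and settles to a 50% plateau through
the simulation horizon; the IL-1β-like input is a lower (40 nM) transient.
Parametric pulses place their rise/plateau/fall switch points analytically
so the 5%-threshold duration equals the requested duration (within 2%,
amplitude-invariant). Pulse trains compose basal-corrected pulses by
pointwise maximum, so overlaps never exceed the single-pulse peak. All
inputs are deterministic.

## Parameterisation and calibration

The reference parameter set (84 rate constants + per-dimer degradation,
87 parameters, 35 functional groups) was produced by staged calibration,
not fitted to quantitative time-series: first the basal steady state
(most RelA sequestered by IκBs, most RelB by p100, low nuclear activity
over a small positive basal IKK2), then the dynamical behavior checklist
(`validate_reference_behaviors`): ~1 h transient response to the brief
pulse in wild type; biphasic chronic response (first peak ~1 h, trough,
second phase from ~3 h, RelA:p50-dominated and persistent beyond 8 h);
biphasic brief-pulse response with an open, progressively strengthening
RelB:p50 late phase in the p100-deficient system; its absence when p52
processing alone is blocked; broadened responses without IκBα; and
amplitude-insensitive, duration-tracking production functions.

Design choices that the calibration surfaced as load-bearing:

- the IκBα negative feedback is strong and phase-lagged (mRNA half-life
  ~46 min, high translation), which simultaneously terminates the
  brief-pulse response in ~1 h and carves the sub-threshold trough that
  separates the two phases under chronic input;
- free IκBα is more IKK2-labile than complexed IκBα, so under a sustained
  plateau the re-synthesised inhibitor is consumed before it can fully
  recapture RelA dimers — this keeps the late RelA:p50 wave above its
  threshold without weakening the early feedback;
- *Relb* induction is RelA-dimer-dominant with a small autoregulatory
  RelB-dimer weight and a long-lived *Relb* mRNA (τ ≈ 6.7 h) and nuclear
  B50 (τ ≈ 12.5 h); the brief-pulse burst deposits mRNA whose translation
  integrates into the late nuclear RelB:p50 wave, while the subcritical
  loop gain keeps the basal state finite and the ±10% sensitivity sweeps
  stable;
- p100 suppresses that wave in wild type kinetically: capture into
  p100:B50 is fast and release slow (the reservoir is effectively
  absorbing on the 16 h experimental timescale, though it is flux-neutral
  at true steady state — the p52 branch is what keeps wild-type basal
  nuclear B50 below the knockout's).

Parameter groups follow a species × function taxonomy (synthesis,
mRNA decay, dimerisation, binding, transport, degradation,
IKK2-responsive degradation, processing) and are numbered Gr-I, Gr-II, …;
the group ordering places Relb synthesis — constitutive transcription, the
four induced-transcription weights and translation — fifth, i.e. **Gr-V**.

## Sensitivity analysis

Each group is one uncertain factor: a multiplicative scalar sampled
uniformly from [1−r, 1+r] (r = 0.10) applied to every member parameter.
Total-effect indices use the Jansen estimator on the two-matrix radial
design, ST_i = E[(f(A) − f(A_B^i))²] / (2 V[f]), with companion Jansen
first-order indices and percentile bootstrap (200 resamples by default)
over sample rows for error ranges; draws that fail to simulate are
discarded, and more than 5% of failures aborts the analysis. The default
readout is the late (6–8 h) basal-corrected nuclear RelB:p50 AUC of the
p100-deficient system under the brief pulse, with re-equilibration per
draw so basal corrections stay consistent. The estimator is validated
against analytic variance decompositions of toy functions. Local
sensitivity multiplies one parameter at a time by 1.1, re-equilibrates,
and scores the normalised basal-corrected change in the same readout.

Default sampling is 1,000 Monte Carlo samples; the bundled acceptance
test runs a reduced design (128 samples over the 35 groups, ≈ 4,700
simulations) whose group ranking is already stable.

## What the synthetic inputs do and do not show

The generator reproduces the *shape classes* of IKK2 activity (brief
spike, spike-plus-plateau, pulse trains) but not measured kinase
time-courses, receptor-level regulation, cell-to-cell variability or
single-cell oscillations (the model is bulk-level by construction).
Passing tests therefore demonstrate that the network topology and the
calibrated rate structure reproduce the qualitative dynamical phenotypes
— durations, phase structure, dimer composition, knockout contrasts,
sensitivity ranking, pulse-train refractoriness and augmentation — not
that the rate constants are the physiological ones. Quantities are
reported in nM, but absolute scales are only meaningful relative to each
simulation's own basal and peak.

## Known limitations

- Induced transcription is linear in nuclear dimer concentration; strong
  stimuli cannot saturate promoters, so very large inputs scale responses
  nearly linearly.
- The basal composition of nuclear NF-κB in wild type is more
  RelB-weighted than EMSA data suggest; at true steady state a
  release-only sequestration cycle cannot suppress nuclear RelB below the
  flux balance, so the wild-type/knockout basal contrast rests on the p52
  branch rather than on p100 capture alone. Stimulated, basal-corrected
  contrasts are unaffected.
- p100 sequestration is modelled at the dimer level (p100:B50 etc.), not
  as higher-order IκBδ multimers.
- A single well-mixed nuclear compartment; no chromatin or gene-expression
  layer beyond the four modelled mRNAs.
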