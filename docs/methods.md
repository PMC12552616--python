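# Methods

## The sensing model

A heteroheptameric αHL pore carries exactly one reactive cysteine, so the
recorded current is a two-state alternating process: *open* (current I_P) or
*adduct* (one hemithioacetal bound, current I_res = ires%/100 × I_P). The
kinetics are

- association: bimolecular in total aldehyde concentration,
  v_on = k_on·C_tot. Only the free (non-hydrated) aldehyde reacts with the
  thiol; with the hydration equilibrium K_hyd = [hydrate]/[free], the same
  rate reads v_on = k_on′·C_free with k_on′ = k_on·(1 + K_hyd). Both forms
  are carried through the package and their identity is asserted in the
  tests;
- dissociation: unimolecular, v_off = k_off, independent of concentration.

Each adduct formation yields one of up to two diastereomers (the new
stereocentre at the hemithioacetal carbon). Diastereomer A is, by
convention, the one with the larger residual level. The branching ratio is
not identifiable from the packaged parameters and defaults to 0.5/0.5;
per-diastereomer dissociation rates default to the analyte-level k_off. Both
are plain fields in the fixture files and can be overridden.

Units throughout: concentrations mM, association constants mM⁻¹s⁻¹,
dissociation constants s⁻¹, currents pA (signed; I_P ≈ −129 pA at −50 mV for
the reference pore), residual levels in percent of I_P computed from
like-signed currents (hence positive).

## Parameter fixtures

One YAML file per pore variant packages the working parameter set:
(AG)₆(AG-T115C) (the reference), (MK)₆(MK-T115C), (AG)₆(AG-G137C) and
(AG)₆(AG-G137C-Ala3) (engineered for diastereomer/isomer resolution). Every
number carries a provenance flag: `printed` (taken from the source
characterization), `derived` (computed from printed quantities, e.g. the
butanal k_off = 1/0.130 s, or a level fixed by a printed Δ I_res%), or
`interpolated` (filled in by the ~0.7%-per-CH₂ level rule, by typical
aldehyde hydration constants, or placed inside the printed Δ I_res% ranges
for the engineered pores). The flags are metadata only; nothing in the code
branches on them.

## Trace simulation

`sample_dwells` draws the latent path with competing exponential clocks:
from the open state the waiting time is exponential with rate
Σᵢ k_on,i·Cᵢ, the entering analyte/diastereomer is chosen proportionally to
its rate contribution, and the adduct dwell is exponential with that
diastereomer's k_off. Concentrations are piecewise constant in time
(mid-experiment solution replacement); because the exponential is
memoryless, a segment boundary truncates the running dwell and re-draws the
residual clock at the new rates — the state itself persists, so dwell
records are merged across boundaries and the strict open/adduct alternation
is preserved. Dwell intervals are half-open `[start, start + duration)`
seconds from t = 0.

`render_trace` converts the path to a sampled current:

- levels: open dwells at I_P, adduct dwells at ires%/100 × I_P;
- acquisition filter: a linear-phase Gaussian FIR whose −3 dB point is the
  configured 10 kHz cutoff (σ_t = √(ln 2)/(2π f_c)). For a piecewise-constant
  signal the filter response has a closed form — each transition contributes
  its step scaled by the Gaussian CDF — so rendering is O(events), not
  O(samples × taps), with plateau values exact;
- noise, two components, both seeded: (i) white Gaussian sample noise of
  configurable RMS (default 1 pA) added after filtering, and (ii) one
  Gaussian level offset per blockade (`level_jitter_pct`, default 0.05% SD).
  The jitter term exists because white sample noise alone would let the mean
  level of a long event be estimated arbitrarily well, whereas measured
  per-event level spreads plateau at roughly 0.05–0.1% for events ≥ 10 ms;
  a per-event offset reproduces that floor and is what limits discrimination
  of closely spaced levels (e.g. butanal vs 2-methylpropanal at ~0.2%
  separation on the reference pore).

Default acquisition: 50 kHz sampling, 10 kHz filter, −50 mV. Determinism:
one scenario seed is expanded into fixed per-stage generators, so identical
scenario + seed gives bit-identical dwell sequences and traces (asserted in
the tests and by the run manifest digests).

What the generator deliberately omits: 1/f and amplifier-specific noise,
baseline drift, gating and spurious blockades, pH dependence of the
chemistry, imine side reactions, solubility limits, and multi-pore arrays.
Tests passing on these synthetic traces therefore show correctness of the
estimators under the stated model, not robustness to every artefact of bench
recordings.

## Event detection

Thresholding is sufficient for a guaranteed two-level signal, so no HMM is
used. The trace is low-passed again at the analysis bandwidth (default
1 kHz) with a triple-boxcar cascade whose impulse response matches the
Gaussian σ for that cutoff (linear phase, O(n) at any bandwidth). A rough
open level (median of the filtered trace, valid below 50% occupancy) places
the decision threshold in ires% units — by default halfway between the open
level and the shallowest expected adduct level, e.g. 99.35% when the
shallowest level is propanal's 98.7%. Blockade runs shorter than the dead
time (default 0.5 ms) are treated as missed; open gaps shorter than the dead
time between blockades are merged, so a single noise excursion cannot split
one adduct dwell in two (unmerged, this measurably inflates v_on at high
occupancy). The final baseline is the median of raw open samples away from
any candidate transition, and per-event features are computed from raw
samples excluding 3 filter time constants at each edge: mean level → ires%,
duration from the threshold crossings, and the within-event standard
deviation → RMS noise. Events with fewer than 3 usable samples keep their
duration but are flagged `short` with undefined features rather than
dropped.

For mixtures whose shallowest level approaches the open level (ethanal at
~99.4% leaves a 0.3% margin), the default 1 kHz bandwidth leaves too much
noise at the threshold; the seven-aldehyde analyses therefore run the
detector at 250 Hz with a 2 ms dead time. This trade (bandwidth vs margin)
is configurable and tested.

## Rate estimation

Detected dwells longer than the dead time t₀ follow a left-truncated
exponential; its MLE is rate = n/Σ(duration − t₀) with stderr = rate/√n,
which reduces exactly to the naive estimator at t₀ = 0. With k_off ≤ ~10 s⁻¹
and t₀ = 0.5 ms the truncation term is the entire correction that matters
(< 1% bias), so no missed-event convolution correction is applied. v_on is
estimated against accumulated *open* time — the association clock only runs
while the cysteine is free — with the symmetric dead-time correction; zero
events yield a 0 with a rule-of-three 95% upper bound. k_on is the
inverse-variance-weighted least-squares slope through the origin of v_on
against total concentration (per-point weights because event counts differ
across concentrations), and k_on′ applies the hydration correction with the
fixture K_hyd.

## Classification and quantification

Events are classified from three features — ires%, log duration, log RMS
noise (the latter two are positive and right-skewed). Two interchangeable
models: a fully self-contained Gaussian-per-class baseline (one mean and
full covariance per class, maximum posterior under equal priors, JSON
serialisable, checked in the tests against a brute-force density oracle) and
a random-forest ensemble (scikit-learn, 300 trees by default) used for the
headline multi-aldehyde accuracy. Training sets are balanced per class, with
a stratified split holding out 30% for testing.

Quantification inverts the bimolecular law per classified analyte:
C_tot = v_on/k_on with the calibration k_on, delta-method standard errors,
and rule-of-three upper bounds for analytes with no events. Because the
observed k_on is defined against total concentration, no hydration
correction enters at quantification time. Segmented recordings (known
solution-replacement times) are analysed per segment and reported as
concentration ratios with first-order error propagation; change-point
detection is deliberately out of scope.

## Desk-scale protocols and problem sizes

`porevoc.protocols` packages the standard runs used by the test suite and
`scripts/acceptance.py`. Recording lengths and concentrations are the
package's own choices, set so each estimate gets the event count it needs
within a few simulated minutes:

| protocol | conditions | yields |
|---|---|---|
| butanal kinetics | 3 mM, 600 s | ~500 events; lifetime ~130 ms; baseline |
| propanal level | 5.8 mM, 240 s | ≥300 events; mean I_res% ≈ 98.7 |
| hexanal level | 5.5 mM, 400 s | ≥400 events; mean I_res% ≈ 96.1 |
| heptanal split | 3.0 mM, 480 s | ≥100 events/diastereomer; ΔI_res% ≈ 0.29 |
| propanal series | 3.0/5.8/8.5/11 mM, 240 s each | k_on → k_on′ ≈ 0.5 |
| mixture | butanal 4 mM + pentanal 2 mM, 600 s | conc. errors < 10% |
| classification | 1000 events × 7 aldehydes, 70/30 split | accuracy ≥ 98% |

Hexanal and heptanal run above their bench characterization concentrations
(2.7 and 1.5 mM) purely to reach the required event counts at desk scale;
rates scale linearly so the estimates are unaffected. The heptanal split
clusters events ≥ 5 ms (two k-means groups on ires%), since shorter events
average too few samples for their level error to stay well below the 0.3%
split. The classification benchmark draws labeled events directly from the
generative model (truncated-exponential durations, jitter + sampling-error
levels, chi-distributed RMS) — the same law the renderer + detector induce,
without paying for seven full 50 kHz traces; trace-level detection fidelity
is covered separately by the recall/precision and level-recovery tests.

## Numerical choices and edge cases

- Tie-breaks/degenerate inputs: zero total association rate gives one open
  dwell spanning the segment; zero events quantify to 0 mM with an upper
  bound; a singular class covariance falls back to its diagonal with a
  warning; empty trace files, NaN samples, unlabeled events, unknown
  analytes and unordered segments raise typed errors.
- The baseline estimator requires at least `baseline_window` (default 0.1 s)
  of open samples and is median-based; above ~50% occupancy the rough median
  pass would land on the adduct level, which is outside the supported regime.
- Text formats round-trip exactly: floats are written at %.17g and parsed
  with round-trip precision.
- Seeds: every stochastic stage derives its generator from the single
  scenario/CLI seed via fixed keys, so partial pipelines rerun alone
  reproduce the full pipeline's artifacts.

## Known limitations

Detection near the open level (shallow blockades such as ethanal's) trades
bandwidth against threshold margin and degrades first; per-analyte excess
blockade noise is configurable but defaults to uniform, so the RMS feature
carries little class information in synthetic data; v_on uses the open-time
denominator (at occupancies below ~15% the total-time convention differs by
less than the reported uncertainties); and the diastereomer branching ratio
and per-diastereomer k_off defaults are assumptions, not measurements.
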