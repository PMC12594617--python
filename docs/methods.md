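# Methods

## The generative model of pain ratings

A participant's reported pain rating on trial *i*, `Y_i` (0–100 visual
analogue scale), is treated as the inversion of a probabilistic generative
model in which three sources of information are each Gaussian-linked to the
latent rating:

* **Stimulation factor** — the rescaled delivered intensity `X_i` is
  modelled as `N(Y_i, β²)`. The precision `1/β²` is the *somatosensory
  weight*: how strongly ratings track what was actually delivered.
* **Cue factor** — the rescaled cue mean `q_i` (average of the two cards
  shown) is modelled as `N(Y_i + η·SD_i, ρ²)`, where `SD_i` is the spread
  of the two cards. `1/ρ²` is the *expectation weight*; `η` is a signed
  scale converting cue uncertainty into a shift of the expected cue value
  (positive η: vaguer cues raise the pain expectation).
* **Trait-like bias** — `Y_i ~ N(μ, ν²)` independent of the trial's
  inputs. `μ` is the participant's intrinsic rating tendency and `1/ν²`
  the weight placed on it.

Multiplying the three factors and normalising over `Y` yields a Gaussian
with precision `1/s² = 1/β² + 1/ρ² + 1/ν²` and mean

    m_i = s² · ( X_i/β² + (q_i − η·SD_i)/ρ² + μ/ν² ),

the usual precision-weighted combination. The reported rating is modelled
as a draw from this collapsed Gaussian, which makes it the exact per-trial
likelihood; this is the unique reading under which MCMC inversion of the
factor product is well posed. The collapse is verified against numerical
quadrature of the unnormalised product (relative error < 1e-6 over 1000
random parameter/input draws).

**Boundary handling.** Forward simulation clips ratings to [0, 100] and
reports the clip rate, warning above 5%. Fitting treats ratings at the
scale boundaries as *censored* observations (tobit likelihood): a rating
of exactly 0 or 100 contributes the Gaussian tail mass beyond the bound
rather than a density value. In calibration runs the naive untruncated
Gaussian visibly biased the bias-factor variance when clip rates were
non-trivial; censoring removes that bias while leaving interior ratings
untouched. The plain Gaussian likelihood remains available
(`censor_bounds=None`).

## Task paradigm

Trials mirror the cued-pain decision task: two integer levels on the 0–10
psychophysics scale (anchors 3 = pain threshold, 7 = highest tolerable)
form the target pair, separated by at least 2 units so that stimulus and
cue information decorrelate; the lure repeats one target card and replaces
the other with a strictly higher level. The delivered level is drawn
50/50 from the chosen pair. Levels and cue means are affinely rescaled to
0–100. Participants failing to pick the target on strictly more than 25%
of trials are excluded.

Two conventions the task description leaves open are fixed here:

* **Cue SD** of a two-card cue is the population SD, `|r(a) − r(b)|/2` on
  the rescaled scale (sample SD `|r(a) − r(b)|/√2` selectable). η's scale
  is arbitrary up to this choice; fixing one keeps fits comparable.
* **Lure sampling** is uniform over the admissible higher cards; only the
  constraint, not the distribution, is prescribed by the paradigm.
* Synthetic participants pick the target with accuracy 0.95 (configurable);
  when they pick the lure, delivery and cue statistics follow the *chosen*
  pair — the cue the participant actually saw — and the trial is flagged.

## Bayesian inversion

Each participant is fitted independently. Sampling runs in the
unconstrained space `(log β_sd, η, log ρ_sd, μ, log ν_sd)` with an
affine-invariant ensemble sampler (48 walkers, 2000 warm-up + 2000 kept
steps, differential-evolution moves). Walkers are treated as chains for
split-R̂ and ESS; fits with R̂ > 1.01 or ESS < 400 on any parameter are
flagged, never silently accepted. Precision summaries (`1/β²` etc.) are
computed per draw and then summarised — by Jensen's inequality the
reciprocal of a summary is not the summary of reciprocals.

**Priors.** Defaults are weakly informative on the 0–100 scale:
half-Cauchy(0, 25) on each factor SD, Normal(0, 1) on η, Normal(50, 30)
on μ. Both non-obvious choices come from simulation-based calibration.
The cue variance ρ² is only weakly identified by 60 trials (the cue mean
co-varies with the delivered level by task design, so the expectation
weight is estimated from a difference of regression effects): a
light-tailed half-Normal SD prior pulls its posterior quantiles upward
and under-covers modest true values, while the heavy-tailed half-Cauchy
leaves ρ² to the data. The η prior is scale-reasoned: the cue shift
`η·SD` must live on the rating scale and cue spreads reach ~50 units, so
|η| of order one already spans the plausible range; a much wider η prior
lets the cue factor absorb arbitrary offsets, which further degrades the
identifiability of ρ² and produces nonsensical η posteriors. A
half-Normal SD option remains available (`PriorSpec.sd_family`), and all
scales are overridable.

**Point estimates** for the correlation stage are posterior means
(medians selectable). Down-weighting or hierarchical pooling across
participants is intentionally absent: participants are scientifically
independent units here.

## EEG features

Epochs are stimulation-locked, −4500 to +500 ms at 500 Hz, with per-trial
markers for pair onset, choice, cue onset and stimulation. Windows are
half-open `[start, end)` at sample resolution (ms offsets floor toward the
earlier sample — one fixed convention, no off-by-one drift):

| window | anchor | offsets |
|---|---|---|
| baseline | pair onset | [−500, 0) ms |
| early anticipation | cue onset | [0, 500) ms |
| late anticipation | cue onset | [2500, 3000) ms |
| post-stimulation | stimulation | P2 peak ± 100 ms |

With the 3 s cue display, late anticipation coincides with the last 500 ms
before stimulation. Baseline correction subtracts the per-trial,
per-channel baseline-window *mean*. The participant ERP averages trials
over [−500, +500) ms around stimulation after pre-stimulus baseline
correction; the P2 electrode is the channel with the highest grand-average
post-stimulus amplitude (ties → first label, logged), and the individual
P2 peak is the maximum of the *signed* amplitude in (0, 500] ms — P2 is a
positive deflection; an absolute-value variant exists for exploration.
Peak windows reaching past the epoch end are clipped and flagged. The
selected electrode is always derived from the data, never hard-coded.

## Correlation stage

ROI activities (10 mm spheres at MNI coordinates, mean activity per
participant) are first pruned for redundancy: within each (structure,
window) group, while any pair's Spearman ρ strictly exceeds 0.7, the
highest-ρ pair is resolved by dropping the sphere farther from the
structure's centre of mass (editable table of MNI centroids; distance ties
drop the later-listed sphere, logged). Greedy highest-first resolution
makes multi-sphere groups deterministic and order-stable.

Hypothesised tests: somatosensory weight vs sensory-processing structures
(postcentral gyrus, middle frontal gyrus, posterior cingulate, inferior
parietal); expectation weight and |η| vs cue-processing structures
(subgenual cingulate, middle/superior/inferior frontal gyri, inferior
temporal gyrus, orbitofrontal cortex); and the trio {somatosensory weight,
|η|, μ} vs P2 amplitude. η enters hypothesis tests as |η| because its sign
encodes direction, not strength. BH-FDR is applied within one family per
(parameter × time window); the P2 trio is its own family. Everything else
— remaining parameter × ROI pairs, the remaining weights vs P2, all
parameters vs questionnaire covariates and the mean rating — is
exploratory: uncorrected p-values, flagged tentative.

Spearman ρ uses tie-corrected average ranks. The p-value is the exact
permutation probability for n ≤ 8 without ties (all n! orderings) and the
`t = ρ√((n−2)/(1−ρ²))` approximation otherwise. Tests default to
two-sided; one-sided is available and used where the design's power claim
is one-tailed.

**Power.** The planned test (one-tailed, ρ = 0.33, α = 0.05) is evaluated
both in closed form, `power = Φ(atanh ρ · √(n−3) − z_{1−α})`, and by
simulating bivariate-normal samples; the two agree within Monte-Carlo
error and both give power ≥ 0.8 at n = 70 and n = 63.

## Synthetic cohorts

The generator reproduces the study conditions — 63 participants, 60 trials
each, anchors 3/7, 50/50 delivery — with known ground truth. Population
defaults, chosen so ratings span the 0–100 scale at low clip rates:
β² ~ logN(log 200, 0.5²), ρ² ~ logN(log 400, 0.5²), ν² ~ logN(log 900,
0.5²), η ~ N(0, 0.5²), μ ~ N(50, 15²). These are testing conditions, not
claims about the human population.

Rank correlations between parameters and ROI/P2 targets are planted via a
Gaussian copula: normal scores of the parameter are coupled to the target
with Pearson r = 2·sin(π·ρ_s/6), the exact bivariate-normal
Spearman↔Pearson relation, so the sample Spearman converges to the target
ρ_s. Unplanted ROI activities and all questionnaire covariates are
independent noise. Synthetic epochs carry a Gaussian P2-like bump (SD
40 ms, latency 250 ± 30 ms) on a designated channel over 1/f-shaped noise,
with bump amplitude rank-linked to a configurable parameter.

One root seed expands into per-participant and per-table substreams
(`numpy` SeedSequence), so a manifest regenerates every table bit-exactly.
Epoched waveforms are generated on demand (`make_epochs` /
`generate_epochs`): a full-cohort waveform set is ~750 MB of transient
array data that only the EEG-feature stage consumes.

**What the generator does not emulate:** learning or drift across trials,
response times, realistic volume conduction or artefacts, correlated
questionnaire structure, and any coupling between EEG noise and the
behavioural parameters. Passing tests therefore demonstrate correctness of
the estimators and analysis logic under the stated model, not robustness
to real-data violations of it.

## Problem sizes and numerical choices

Recovery checks use 50 participants × 60 trials; planted-effect detection
uses 20 cohorts of 63; null calibration uses 100 cohorts; power
simulations use 20,000 replicates. The ensemble log-posterior is evaluated
vectorised across walkers; positions outside generous hard bounds
(SD ∈ [e⁻³, e⁹], |η| < 50, μ ∈ [−500, 600]) return −∞ to keep
exponentials finite. Quadrature oracles integrate over Y ∈ [−500, 600]
with Simpson's rule on 20k-point grids.

## Known limitations

* Correlating planted effects against *fitted* rather than true parameters
  attenuates them (estimation noise in the ranks); end-to-end detection
  rates against fitted weights are accordingly lower than against truth.
* The cue-uncertainty scale η is only identified through variation in cue
  spread (three distinct values under the default task), so its posterior
  is wide at 60 trials; sign recovery is reliable only for |η| ≳ 0.5.
* Numerical equality with any specific HMC implementation is not claimed;
  sampler correctness is established by the recovery suite.
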