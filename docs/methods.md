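# Methods

This note documents the models, estimators and numerical choices behind
`ddrcyto`, and what the synthetic-data verification does and does not
establish about real data.

## Measurement model and transforms

CyTOF channels report non-negative ion counts that are heavy-tailed and
zero-inflated (a metal-tagged antibody either binds and is counted, or the
event records zero). All event-level *classification* (gating,
debarcoding, singlet/viability filters) operates on the arcsinh scale,
x ↦ asinh(x / c) with cofactor c = 5, the community default for mass
cytometry; the cofactor is configurable. The transform is applied at most
once per frame (a state flag enforces this) and the raw matrix is retained,
because all *intensity statistics* are computed on the raw scale.

**Geometric MFI.** The per-population marker summary is the geometric mean
of strictly positive raw intensities, matching the geometric-MFI convention
of mainstream cytometry software. Zeros are excluded (a geometric mean over
a zero-inflated sample is otherwise degenerate) and the exclusion is
counted (`n_positive`). Cells with fewer than `min_events = 30` positive
events return a missing value with a flag rather than an unstable estimate.
Because the generator scales only the lognormal (positive) component of a
DDR channel, this estimator is unbiased for the simulated fold on the
population level.

**Fold induction** is per-donor: each (donor, population, marker) trace is
divided by the same donor's untreated time-0 geometric MFI. All of a
donor's time points were barcoded, pooled and stained in one tube, so the
untreated sample is the natural within-donor reference; cross-donor
summaries are means (± SD) of per-donor folds. The fold at t = 0 is exactly
1 by construction; missing references propagate as flagged missing values.
Fold induction is scale-equivariant in the right way: rescaling a channel
multiplies geometric MFIs but leaves folds unchanged.

## Preprocessing gates

* **Singlets**: the main density mode of Ir191 ± 3·MAD, with the same band
  (shifted by the estimated inter-channel mode offset, which absorbs the
  Ir193/Ir191 isotope-abundance ratio) applied jointly to both DNA
  channels. Doublets carry ≈2× DNA and fall above the band. A ±3·MAD band
  equals ±2.02 σ for a Gaussian mode, i.e. ≈95.7% nominal singlet
  retention per channel; the joint gate retains ≥95% only because the two
  iridium channels read the same intercalator signal and are therefore
  modelled (and in practice observed) as nearly perfectly correlated.
* **Viability**: cells are kept if the cisplatin channel lies below the
  density valley between the live (low) and dead (high) modes; if no dead
  mode is present the bound falls back to mode + 6·MAD, effectively open.

Both gates are per-event filters, hence commutative and idempotent; the
pipeline logs events-in/events-out per stage.

## Debarcoding

Single-cell separation deconvolution of the 3-of-6 palladium scheme
(20 possible keys): per Pd channel, intensities are rescaled to [0, 1] by
the 1st–99th percentile range computed on the pooled file; the event's
separation is the gap between its 3rd- and 4th-highest rescaled channels;
events below the cutoff (default 0.30) or whose top-3 pattern is not in
the code book are left unassigned. Doublets of two differently-keyed cells
have ≥4 high channels and near-zero separation, so they are rejected here
as well as by the DNA gate. A constant Pd channel makes the rescaling
ill-conditioned and raises a configuration error — which is why the
generator's default key assignments are balanced subsets in which every
channel is high in some pooled samples and low in others. No Mahalanobis
refinement pass is applied; the stage stays auditable and its accuracy is
scored against ground truth instead.

## Threshold estimation and gating

Per-marker thresholds are estimated from a binned kernel density estimate:
histogram on a 512-point grid smoothed with a Gaussian kernel, Silverman's
rule bandwidth floored at 1% of the data range (zero-inflated channels
otherwise drive the rule toward zero and a jagged estimate). Modes are
detected on the **log** density — a peak must rise at least a factor 2
above its saddle, lie ≥0.5 transformed units from the next mode, and clear
a small height floor — so that a positive population of a few percent is
found next to the enormous zero spike of a negative channel without
picking up histogram noise.

* t1 is the deepest density minimum between the two largest modes
  (ties, i.e. empty gaps, resolve to the gap centre).
* Unimodal channels fall back to the 0.95 quantile — correct for channels
  whose positives are too rare to form a mode. CD45 is the exception:
  every analysed event is CD45⁺, so its unimodal distribution *is* the
  positive one and t1 is placed at mode − 3·MAD instead (configurable
  `always_positive` set).
* Markers used at two levels (CD56 dim/bright, IgM⁺⁺, CD38⁺⁺) get
  t2 = midpoint between t1 and the uppermost mode (or the 99.9th
  percentile when no mode lies above t1).

Thresholds are estimated once per donor on the pooled cleaned events of
all time points — the tube was stained once, so one threshold set keeps
time points comparable — and written to CSV with provenance.

Populations are conjunctions of level predicates arranged in a tree;
children inherit parental predicates, so child ⇒ parent membership holds
structurally, and overlapping memberships (an event is CD3⁺ *and* naïve
CD4) are intentional: every statistic is computed per population
independently. "high"/"bright"/"++" all map to ≥ t2; "low" maps to < t1
(low is not distinguished from negative, as for CD21^low CD38^low B).
The literal CD19⁺CD20⁺CD27⁺ definition of memory B is kept; it excludes
plasmablasts only through the CD20⁺ requirement.

Cell cycle: ki67⁺IdU⁺ = S, ki67⁺IdU⁻ = G1, ki67⁻IdU⁻ = G0, and
ki67⁻IdU⁺ — a transient replication-arrest state seen after UVC — is kept
as its own class rather than folded into S. Stratified kinetics normalise
within stratum (each stratum has its own untreated reference).

## Statistics

Fold tables are compared with a fixed-effects two-way ANOVA
(`fold ~ population * timepoint`, per-donor folds as replicates, no
blocking on donor), whose residual mean square serves as the pooled error
for Tukey HSD comparisons between populations within each time point
(studentized-range p values; Tukey–Kramer form for unequal n). With a
single time point this reduces exactly to one-way Tukey HSD, which the
test suite cross-checks against an independent implementation. If the
interaction model has no residual degrees of freedom the additive model is
used. Side-by-side paired comparisons use Šídák adjustment
p_adj = 1 − (1 − p)^m; Student's t is pooled-variance (no Welch
correction), two-sided, with p = 1 by convention for degenerate
zero-variance equal-mean input. Stars: \*p ≤ 0.05, \*\*p ≤ 0.01,
\*\*\*p ≤ 0.001, \*\*\*\*p ≤ 0.0001 (inclusive thresholds). No additional
correction is applied across markers. Under a shared-response null the
Tukey-adjusted comparisons are significant ≈4% of the time (familywise
control makes the per-comparison rate conservative).

## The synthetic experiment generator

The generator emulates the study design end-to-end so that every stage of
the pipeline can be scored against known truth; one integer seed
determines the whole experiment.

* **Design**: per donor, five time points (untreated + 1/4/8/24 h after
  IR 2 Gy or UVC 100 mJ/m²), each tagged with a Pd key and pooled into one
  frame; default cohorts of 26 healthy and 3 AT donors, 20,000 events per
  time point at full scale.
* **Composition**: viable CD45⁺ events split into 21 leaf subsets —
  T 75.5% (naïve 37.6%, CM 10.5% of T on the CD4 side, with analogous CD8
  splits), NK 7.0% (75% CD56^dim CD16⁺), B 8.1% (naïve 52.3%, unswitched
  memory 34.1% of B), remainder unclassified — anchored to the reported
  baseline means. Each sample's composition is jittered (lognormal,
  CV 10%) to emulate handling variability; this is what keeps small true
  composition shifts from being trivially significant under paired tests.
* **Expression**: marker levels per subset are tokens (neg / pos / dim /
  bright) mapped to zero-inflated lognormals on the raw scale (pos: median
  150, CV 0.8; dim: 60; bright: 2500) over a half-normal background;
  DDR channels share a per-marker baseline median across subsets so
  composite populations have closed-form expected folds (weighted
  geometric means of leaf folds).
* **Kinetics**: fold(t) = 1 + A·(t/t_p)·e^(1−t/t_p) — the simplest smooth
  pulse with fold(0) = 1, a single maximum of exactly 1 + A at t_p, and
  decay to baseline. Defaults encode the qualitative response structure:
  γH2AX amplitudes NK > T > B; p-CHK2 dominated by B cells (A = 4 vs ≈1
  elsewhere); p-ATM elevated in NK; naïve T with lower γH2AX but higher
  p-ATM/p53 than memory; t_p = 1 h for the early markers after IR and 6 h
  after UVC; p53 peaks at 8 h. Donor-to-donor response variability is a
  mean-1 lognormal factor (CV 15%) on each amplitude.
* **Survival**: multiplicative subset survival over time; only B cells
  decay by default (s(24 h) = 0.535, chosen so the B share of viable
  CD45⁺ falls from ≈8.1% to ≈4.5%). T and NK survival is 1, so their
  24 h shares rise slightly (to ≈78.5% and ≈7.3%) by renormalisation —
  close to, but not exactly, the reported 77.2%/7.2%, which are empirical
  means not constrained to renormalise.
* **AT donors**: all amplitudes scaled to 0.02× (well under the ≤0.1×
  abrogation bound), except a retained partial γH2AX response (absolute
  amplitude 0.15) in effector-memory T and CD56^bright NK cells, reflecting
  compensation by other PIKK kinases; the retained amplitude is small
  enough that every true AT fold stays within [0.8, 1.2]. AT B-cell
  survival at 24 h is 0.30, below the healthy cohort's.
* **Artifacts**: 10% dead cells (cisplatin-high) and 2% doublets
  (channel-wise sums of two random events, so both the DNA gate and the
  barcode separation can catch them). The DNA channels are modelled as
  near-perfectly correlated reads of one per-cell DNA content (lognormal,
  σ = 0.12) — see the singlet-gate note above.

**What the generator does not emulate**: acquisition drift and bead
normalisation, spillover between channels, event length, biological
marker correlations beyond the subset structure (e.g. continuous
CD45RA/RO gradients), batch effects, and realistic independent Poisson
counting noise on the two iridium channels. Passing the verification suite
therefore shows that the estimators recover truth under the stated
measurement model at the stated sizes; it does not certify performance on
instrument-specific artifacts outside that model.

## Verification workloads and problem sizes

The acceptance workloads run the complete pipeline (simulate → transform →
clean → debarcode → gate → quantify → compare) at desk scale on one CPU:

* fold recovery: 26 donors × 5 time points × 4,000 events; worst
  cohort-mean relative error over populations ≥ 2% of viable CD45⁺
  (observed ≈5–7%, bound ±10%);
* orderings: 20 seeds of 5 donors × {0, 1 h} × 2,000 events;
* AT discrimination: 20 seeds of (10 control + 3 AT) donors × {0, 1 h} ×
  20,000 events (full per-time-point depth, because the [0.8, 1.2]
  abrogation band is checked on per-donor fold estimates, whose noise
  scales with event count), plus one full five-time-point AT cohort;
* debarcoding: one pooled donor, 12,500 singlets plus injected doublets;
* gating: one donor, 50,000 events;
* statistics: 200 null repetitions at the kinetics-table level;
* survival detection: 10 seeds of 8 donors × 5 × 2,500 events.

These sizes are the package's default benchmark configuration; all
generator parameters in the workloads are the defaults described above.

## Numerical and degenerate-input choices

* Density grids are fixed at 512 points; all estimators are deterministic
  given the data (no sampling), so thresholds are exactly reproducible and
  pipeline reruns are byte-identical.
* Ties in valley finding resolve to the centre of the tied run; t2 falls
  back to the 99.9th-percentile midpoint when no upper mode exists; an
  estimated t2 ≤ t1 is nudged to t1 + 1e-6.
* Empty frames pass through the gates; an all-dead sample yields an empty
  output with a logged warning; a zero CD45⁺ denominator yields flagged
  missing survival values.
* FCS: only the first dataset of a multi-dataset file is read (warning);
  reading supports `$DATATYPE` F and I (with `$PnR` bit masking), writing
  always emits FCS 3.1 float32 little-endian. Roundtrips preserve
  intensities to float32 precision.
* Seeds: a master integer seed feeds `numpy` `SeedSequence` spawning, one
  stream per donor; derived benchmark seeds stay below 2³¹.

## Known limitations

* Rare populations (transitional B, plasmablasts, IgGκ/λ switched memory;
  < 0.5% of events) sit below the mode-detection prevalence at default
  sizes; their thresholds come from quantile fallbacks and their
  frequencies are correspondingly less accurate. They are excluded from
  the ≥2% recovery bound for this reason.
* The ±3·MAD singlet band is intrinsically at ≈95% joint sensitivity; a
  wider band trades doublet leakage for retention and can be set in the
  pipeline config.
* Geometric MFIs on raw ion counts are sensitive to the positives-only
  convention when zero-inflation differs between conditions; the generator
  holds zero-inflation constant, real instruments may not.
* The statistics layer implements fixed-effects ANOVA only; donors are
  replicates, not a random effect.
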