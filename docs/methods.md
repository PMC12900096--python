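# Methods

`cardiocl` implements anatomy-aware contrastive self-supervised learning
for multi-lead ECG: physiology-preserving view generation, one independent
1D-CNN encoder per lead, fusion of lead embeddings into four myocardial
regions, a dual intra-/inter-region InfoNCE objective, and linear-probing /
fine-tuning transfer evaluation. A synthetic ECG generator makes the whole
pipeline testable at desk scale on a CPU.

## Preprocessing

The 12-lead system is linearly redundant: with Einthoven's law and the
Goldberger definitions, I = II − III, aVR = −(I + II)/2, aVL = I − II/2,
aVF = II − I/2, so leads I, aVR, aVL, aVF carry no information beyond II
and III. The pipeline retains (II, III, V1…V6) in that fixed order,
standardizes duration to 10 s (head-truncate / zero-pad at the end),
resamples every lead to a common length (default 2048 samples) with the
band-limited Fourier method (`scipy.signal.resample`; the 5000→2048 ratio
is non-integer, so naive decimation would alias), and z-score-normalizes
**globally** — one mean and standard deviation over all leads and time
points of a record — so inter-lead amplitude relations survive
normalization. Normalization is per record, not per dataset. No filtering
(baseline wander, power line) is applied anywhere; that is a property of
the modeled pipeline, not an omission, and it is why the synthetic
generator must supply realistic nuisance structure (below).

A note on the aVL formula: the source formulation is typographically
ambiguous; `aVL = I − II/2` is adopted because, under Einthoven's law,
it equals the standard Goldberger identity (I − III)/2 and satisfies
aVR + aVL + aVF ≡ 0, whereas the alternative reading (I − II)/2 reduces
to −III/2, which is not a valid augmented lead.

## View generation

Three rhythm-preserving augmentations compose (RRC → CCM → TS) into
independent draws for the two views of each record:

* **Random resized crop (RRC)** — a random 80–100 % subsequence, Fourier-
  resampled back to the target length (same interpolation as
  preprocessing).
* **Cardiac-cycle masking (CCM)** — R-peaks are detected on lead V5 of the
  operation's *input* (i.e. re-detected after cropping), the mean RR
  interval defines the cycle, and one contiguous window of 20 % of the
  cycle is zeroed strictly inside every complete inter-peak cycle, on all
  leads simultaneously; a window never touches an R-peak, and nothing
  before the first or after the last detected peak is masked. If fewer
  than two peaks are detectable, a nominal 0.8 s cycle grid is used.
* **Temporal shift (TS)** — one integer offset, uniform within ±80 % of
  the length, applied to all leads with zero padding.

The composition order is a design choice: CCM needs reliable R-peak
detection, which TS's zero padding would corrupt, so TS runs last. Each
enabled operation is always applied (no per-operation probability).
No operation rescales amplitudes or injects noise; the only new sample
value is zero. Views are drawn freshly every epoch from a
per-(epoch, record) random substream, so the data-loading order cannot
change the draws.

## R-peak detection

A classical Pan–Tompkins-style detector (band-pass 5–15 Hz zero-phase,
derivative, squaring, 150 ms moving-window integration, peak picking with
a 250 ms refractory period, refinement to the local raw-signal maximum)
keeps the artifact self-contained and deterministic; the `detector`
argument lets an external toolkit replace it for real data. Detection for
CCM runs at the post-resampling frame with the effective sampling rate.

## Model

Each lead has a dedicated VGG-style 1D encoder with independent
parameters: four stages of two (conv k=3, pad 1 → batch norm → ReLU)
blocks followed by max-pool stride 2, then global average pooling. Base
widths (64, 128, 256, 512) are scaled by α = 0.125, giving widths
(8, 16, 32, 64) and a per-lead embedding of m = 64 — one eighth of a
conventional 512-dim multi-lead encoder. The exact stage/kernel layout is
an implementation realization (the reference architecture is specified
only by style) and is isolated behind `ModelConfig`. Global average
pooling makes the architecture length-agnostic; input lengths
{512, 1024, 2048, 4096} all work, with the constraint that the length is
divisible by 2⁴.

Lead embeddings fuse by concatenation into D = 4 anatomical regions —
anterior (V3, V4), inferior (II, III), septal (V1, V2), lateral (V5, V6) —
each projected by a region-specific 2-layer MLP (2m → 2m → 128,
SimCLR-style; the projector shape is a design choice). A `random`
grouping mode partitions the 8 leads into 4 random disjoint pairs
(ablation arm). Downstream tasks discard the projectors and use the
8m = 512-dim concatenation of all lead embeddings.

Because no autodiff framework is available in the target environment, the
layers, Adam, and all backward passes are implemented directly in NumPy
(`cardiocl.nn`); every backward pass is pinned by finite-difference
gradient checks in the test suite.

## Loss

For batch size N (2N views), region projections z_k^d, cosine similarity
s and temperature τ = 0.1, the per-anchor intra-region loss sums over
d = d′ the NT-Xent term

    −log  exp(s(z_i^d, z_j^d)/τ) / Σ_{k≠j} exp(s(z_i^d, z_k^d)/τ)

and the inter-region loss sums the analogous term over ordered pairs
d ≠ d′, scaled by 1/(D−1) so its D(D−1) terms do not dominate the D
intra terms. The total is γ·intra + (1−γ)·inter with γ = 0.5. The batch
loss is the mean over all 2N anchors (both views anchor once,
symmetrized); values are therefore batch-size-comparable per anchor.

Two denominator conventions are implemented. The default follows the
printed formulation literally: only the positive k = j is excluded, so the
anchor's self-similarity remains among the 2N − 1 denominator terms. The
`exclude_anchor` switch gives the conventional NT-Xent form (exclude
k = i). Both coincide on the degenerate all-identical-projections batch,
where every component equals D·ln(2N−1) — the closed form used as a test
anchor. Note that the inter-region term as printed *aligns* cross-region
projections of the same instance against batch negatives; it is an
alignment term, not a repulsion, despite the "inter-region
distinctiveness" narrative — the implementation follows the equation.

Numerics: log-sum-exp with max subtraction; cosine norms guarded at
1e−12. The analytic gradient (through the softmax terms, the similarity
matrices and the vector normalization) is validated against central
differences and against a deliberately literal nested-loop oracle
implementation that shares no code with the fast path.

## Pretraining

Adam, learning rate 1e−3, batch size 64, 200 epochs, no scheduler
(defaults; the desk-scale profile below uses batch 8 and 20 epochs).
Incomplete trailing batches are dropped (the loss semantics assume a
fixed 2N). Pretraining is label-blind by construction — the loop never
reads the label field — and fully reproducible from (config, seed):
shuffling and per-record view draws come from named substreams.
Checkpoints (single npz archive: config, all parameters, batch-norm
running statistics, optimizer state) round-trip bit-exactly, and a
resumed run reproduces an uninterrupted one.

## Evaluation

Splits are subject-wise: 20 % of subjects to test, the rest 9:1 into
train/validation, so no identity appears in two partitions. Linear
probing freezes the encoder (used in eval mode as a feature extractor)
and trains a softmax head on the 512-dim global feature (100 epochs,
lr 1e−3); fine-tuning updates everything at lr 1e−4; training from
scratch (TFS) is the identical architecture and optimization from random
initialization. Epoch selection is by validation macro AUROC (the
selection policy is a design choice; last-epoch weights are an
alternative the source does not disambiguate). Label-fraction
experiments subsample whole subjects, stratified so every class keeps at
least one record, and both comparison arms see the identical subset per
(fraction, seed).

AUROC uses the midrank (Mann–Whitney) convention and AUPRC the
average-precision step rule (both via scikit-learn; brute-force pairwise
and step-sum oracles verify them in tests). Multi-class metrics are
one-vs-rest, macro-averaged arithmetically. Threshold-0.5 confusion
counts are reported for completeness and never used for selection.

## Synthetic generator

Beats are sums of five Gaussian bumps (P, Q, R, S, T) with amplitudes,
centers and widths in cycle-fraction units — the standard simplification
of dynamical ECG models. All leads share the bump sum up to per-lead
amplitude factors with V5 strictly dominant, so R-peak ground truth is
well defined on the reference lead. Records tile RR-jittered cycles
(multiplicative Gaussian jitter, truncated ±30 %) at a per-subject heart
rate drawn from 55–85 bpm; each subject also carries mild per-lead
amplitude variation (±10 %).

Class identity is an ST-segment baseline offset applied between the S and
T wave centers on the lead pair of one anatomical region (class →
region), which directly exercises anatomy-aware grouping. Three nuisance
components make the task non-trivial, mirroring real recordings that the
modeled pipeline does not filter: white noise (σ = 0.1 a.u. against an R
amplitude ≈ 1.3), low-frequency baseline wander (0.15–0.45 Hz sinusoid,
amplitude ≈ 0.2 with per-lead amplitude and phase), and per-cycle
amplitude modulation (σ = 5 %). The ST-offset magnitude varies per record
(uniform 40–100 % of the 0.25 a.u. maximum), so the class signal is a
distribution rather than a constant. An earlier, cleaner default made the
task linearly separable from *random* encoder features, which says
nothing about representation quality; the nuisance structure exists so
that a pretraining benefit is expressible at all.

What a green end-to-end test establishes: on quasi-periodic multi-lead
signals with region-localized class morphology and realistic nuisance
structure, contrastive pretraining with this loss and augmentation family
produces features that transfer better than random initialization, and
fine-tuning from the pretrained state is more label-efficient than
training from scratch. What it does not establish: performance on real
arrhythmia/morphology taxonomies, robustness to pathological rhythms
(AF, ectopy), electrode artifacts beyond sinusoidal wander, or any
clinical claim.

## Desk-scale profile and numerical choices

The end-to-end acceptance task uses 400 records (40 subjects × 10), four
classes mapped to the four regions, input length 512 (a value from the
reference length sweep; 4× cheaper than 2048 on CPU), α = 0.125, batch 8,
20 pretraining epochs, and 20-epoch downstream runs with validation every
4 epochs. At this scale (10³ optimizer steps) the intra-region loss falls
steeply (≈ 60 %) while the inter-region loss — cross-region alignment of
the same instance against batch negatives — declines an order of
magnitude more slowly; substantial inter-region reduction requires the
10⁵-step regime of a full-scale run. R-peak index remapping after
resampling rounds half-up and
tolerates 1-sample discrepancies. Crop lengths round half-up; shift
offsets are integers. Records shorter than two cardiac cycles at the
slowest configured heart rate are rejected. Quality-control thresholds
(minimum length 10 s, no missing leads) are configuration, not constants,
because the source pipelines state no numeric values.

## Known limitations

* The inter-region loss follows the printed equation (cross-region
  alignment); if the narrative "repulsion" semantics were intended, the
  objective would need a sign change that is deliberately not implemented.
* The NumPy training stack is single-threaded BLAS-bound; it is meant for
  desk-scale verification, not full-scale pretraining.
* The generator does not simulate arrhythmia morphology (AF, PVCs),
  torso-model lead fields, or electrode dropout.
* WFDB input/output is not available in the target environment; the
  matrix CSV + JSON sidecar format is the interchange format.
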