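# Methods

## Model and assumptions

The pipeline treats subject-level diagnosis as an aggregation of many weak
slice-level decisions. Its core assumptions are:

- **Co-registration.** All volumes share one voxel grid; position m along a
  direction means the same anatomy in every subject. Nothing in the package
  registers, resamples, or skull-strips — that is upstream preprocessing.
- **Compact lesion.** The class difference is confined to one or two compact
  regions, so it appears in a *contiguous block* of slice positions in each
  of the three directions. This is what licenses both the run-length filter
  and the separable intersection.
- **Weak slice labels.** Every slice of a patient is labeled 1 during
  training even though most patient slices are normal. Models at non-lesion
  positions therefore learn (at best) nothing; the run-length filter is the
  mechanism that absorbs their noise at test time.

Axis convention: axis 0 = direction 1 (cross-section), axis 1 = direction 2
(sagittal), axis 2 = direction 3 (coronal); indices 0-based, intervals
half-open. Slices are flattened row-major over the remaining axes in
ascending axis order; the order is arbitrary but train and test share the
single extraction code path, so consistency holds by construction.

## Slice voting

Each (direction, position) random forest classifies a test slice by a hard
majority vote over its trees: positive iff strictly more than half the
trees vote class 1, ties to class 0. This is deliberately *not* the
soft-vote rule (argmax of averaged leaf class fractions) that
scikit-learn's `predict` applies. The two rules differ materially on
uninformative slices: on a constant-feature slice every tree collapses to a
single leaf whose class fraction is its bootstrap's class share, so the
soft-voted probability sits at 0.5 ± ε with a random sign per model, and
about half of all uninformative position models then fire positive for
every subject. Under hard voting, each tree votes its bootstrap *majority*
(ties to 0), which biases individual trees toward the negative class just
enough that the forest majority almost never fires — and increasingly
rarely as trees are added. On a zero-noise phantom the difference is
dramatic: localization IoU ≈ 0.12 under soft voting versus 1.0 under hard
voting at the same seeds.

Per-model determinism: model (d, m) is seeded from
`SeedSequence((seed, d, m))`, so a bank is reproducible regardless of
training order or parallelism. Models are fitted one design matrix at a
time; nothing ever materializes all D1+D2+D3 matrices at once, which keeps
full-scale cohorts (hundreds of subjects, ~17.5k features per slice)
feasible in ordinary memory.

Class imbalance is not reweighted by default (a `class_weight="balanced"`
switch exists). No intensity normalization is applied; raw gray values
pass through.

## Decision rule

`run_filter(v, k)` zeroes every maximal run of 1s shorter than k and
reports the retained runs. k = 1 is the identity (exposed for ablation);
the operating default is k = 3. The filter is idempotent and monotone in k
(filtered(k+1) ≤ filtered(k) elementwise), which makes the diagnosis
monotone non-increasing in k — larger k can only switch positives to
negatives.

The intersection mask is the boolean outer product of the three filtered
vectors, so it is nonempty iff each direction retains at least one run;
that nonemptiness *is* the diagnosis. All runs are retained, not just the
longest, so multi-region findings survive: two runs in one direction times
one in each other direction yields two boxes. The filter is applied per
direction *before* intersecting; with the separable product the two orders
are equivalent for diagnosis, but filtering first keeps the reported runs
interpretable as per-direction findings.

`common_region` intersects masks across subjects voxelwise; it is
commutative, associative, and shrinking (adding a subject never grows the
common region). Because such intersections need not be separable,
`region_report` falls back from run-product boxes to generic 6-connected
components (scipy.ndimage) for its per-component summaries.

## Threshold selection

`select_k` evaluates a grid of k values (default {2, 3, 4, 5}) on pooled
stratified cross-validation accuracy. Slice predictions do not depend on
k, so one CV pass of bank training supplies decision vectors that every k
reuses; accuracy differences across the grid therefore isolate the decision
rule. Ties resolve to the smallest k. Accuracy is pooled over folds
(micro-average), and folds are stratified by label because realistic
cohorts are imbalanced.

## Synthetic phantoms

`generate_cohort` builds each volume as

    baseline + smooth subject jitter + i.i.d. voxel noise + label · effect · 1{lesion}

- **baseline**: a centered soft ellipsoid (intensity 100 inside, 0 outside,
  Gaussian-smoothed, σ = 1.5 voxels) giving slices brain-like nonstationary
  structure, or a flat constant 100.
- **lesion**: one or two axis-aligned boxes; the effect is an additive mean
  shift in intensity units (a multiplicative percent-scaling variant is
  exposed), the simplest proxy for a localized structural difference. A
  morphological (deformation) lesion is out of scope.
- **noise_sd**: i.i.d. Gaussian voxel noise. **subject_jitter_sd**: a
  smooth per-subject field (Gaussian-filtered white noise, σ = 3 voxels,
  rescaled to unit voxelwise sd) modelling anatomy-scale subject
  variability; default 0.
- Reference conditions, fixed once: 24×28×24 grid, 20 controls +
  20 patients, one 4×5×4 box at (10:14, 11:16, 10:14), effect 10,
  noise_sd 2. This keeps a full 5-fold CV of the pipeline in the
  low-minutes range while the lesion still spans more than k slices in
  every direction.

What phantoms do not emulate: MRI physics (bias fields, partial volume,
motion), inter-site heterogeneity, anatomical variability beyond smooth
jitter, and lesions that deform rather than shift intensity. Passing the
phantom battery shows the machinery is correct and recoverable under the
stated noise model — not that real-data accuracies transfer.

## Numerical and degenerate-input choices

- Vote ties (even tree counts) → class 0, conservative toward
  non-diagnosis.
- `localization_overlap` (IoU) of two empty masks is defined as 1.0; the
  mean IoU of a recovery experiment with no true positives is reported as
  0.0.
- Axes of length 1 are legal everywhere (slicing round-trips cover shapes
  down to 1×1×1).
- Fold seeds and model seeds derive from user seeds via `SeedSequence`,
  kept below 2³¹.

## Known limitations

Models at positions whose slices carry no class signal vote near chance on
unseen subjects. With per-direction slice counts in the dozens, chance-level
votes produce spurious runs of length ≥ 3 often enough that some controls
satisfy the all-three-directions rule, and spurious runs inflate
true-positive masks with extra outer-product boxes. On the reference noisy
phantom (noise_sd 2, i.i.d.) this caps pooled CV accuracy around the
mid-0.8s and mean lesion IoU well below the noise-free case — an intrinsic
property of the weak-label slice ensemble at this scale, clearly visible in
the acceptance report's `noisy_*` entries. On real structural MRI,
neighboring slices are strongly correlated and partially informative, a
regime the i.i.d.-noise phantom deliberately understates. Larger k
suppresses spurious runs at the cost of missing thin lesions; `select_k`
makes that trade-off measurable.

The acceptance script's problem sizes (40 subjects, 24×28×24 voxels,
50 trees) are the package's reference desk-scale conditions; the method
itself accepts arbitrary consistent shapes and the published
full-scale settings (700 trees) are the `BankConfig` defaults.
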