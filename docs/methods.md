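# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer should know about.

## MS quantitation

A peptide-spectrum match (PSM) is retained when it has at least
`min_product_ions` product ions (default 15) **and** an ion score of at
least `min_ion_score` (default 30); both comparisons are inclusive, because
"a threshold of 30" and "at least 15" naturally include the boundary. A
protein is positively identified when at least
`min_validated_signature_peptides_per_protein` (default 1) of its retained
PSMs carry `validated = true`. Manual CID-spectrum validation cannot be
automated, so `validated` is an input column, never computed. The
`FilterCriteria` record also carries the upstream search tolerances
(3.0 Da peptide, 2.0 Da fragment) and the admitted modification deltas
(Met +16, Cys +57) for provenance; peptide-spectrum matching itself is out
of scope, so these do not re-filter rows here. Filtering is idempotent and
monotone in every threshold (tested).

Quantitation of the signature peptide uses the apex of the extracted ion
chromatogram — the "100% abundance" value — not the integrated area; the
reference workflow quantifies by apex, and `peak_area` is provided as an
opt-in alternative. No smoothing or baseline subtraction is applied by
default (`subtract_baseline` subtracts the window minimum when asked). The
normalized fold change divides the target peptide's treated/control apex
ratio by the spiked-in control peptide's ratio, cancelling loading and
instrument-response drift; it is invariant under common scaling of all four
apexes (tested). Reported folds round half-away-from-zero to two decimals;
all computation keeps full precision. Note the reference worked example
prints apexes 1.3e6 / 5.5e5 alongside a ratio of 2.47 although direct
division gives 2.36 — presumably unrounded apexes were used; the printed
ratios (2.47, 0.79) are treated as the authoritative inputs to the
normalization step.

`peptide_mz` computes `(Σ residue masses + water + z·proton) / z` via
pyteomics in either monoisotopic or average mode. Both modes matter in
practice: the average-mass [M+2H]²⁺ of LLVSASQDGK (509.58) sits inside the
509.5–511.5 instrument window while the monoisotopic value (509.28) falls
just below it, so window checks default to nothing and let the caller pick
the mode.

## Confocal colocalization

Each z-slice of the nuclear-stain channel is thresholded independently —
per-slice Otsu by default, or a fixed threshold for full determinism — and
binarized with a strictly-greater-than comparison so zero-background voxels
never enter the mask. Constant slices yield an all-zero plane. In Otsu
mode a slice is additionally zeroed when Otsu's effectiveness metric
η (between-class variance over total variance at the chosen threshold)
falls below `min_effectiveness` (default 0.75). This guard exists because
Otsu always returns *some* threshold: on a slice containing only background
noise it splits the noise distribution and masks roughly half the plane.
Pure Gaussian noise attains η ≈ 0.64; genuine nuclear cross-sections score
≥ ~0.8 even when small, so 0.75 separates the two regimes with margin. On
synthetic stacks the guard raises mask Dice against ground truth from
~0.92 to ~0.985; it can be disabled (`min_effectiveness=0`) and never
applies in fixed mode. No morphological post-processing (hole filling,
opening) is applied by default.

The binary mask multiplies the signal channel plane-by-plane;
masked-in plus masked-out intensity reconstructs the original voxelwise
exactly. The nuclear fraction is intensity-weighted by default (robust to
the choice of a signal threshold); the "pixel counting" variant — fraction
of signal-positive voxels inside the mask, signal-positive meaning above a
stated threshold, global Otsu over the signal volume when none is given —
is provided because pixel counting is how such estimates are often
reported. The translocation fold is the ratio of nuclear fractions
(treated over untreated); a ratio of absolute nuclear intensities is
obtainable from the returned `nuclear_signal` fields when preferred.
Per-nucleus statistics use 26-connected components of the mask; each
component's fraction is its signal over the whole-field signal, so
per-cell fractions sum to the field fraction. `upsample_z` replicates
planes nearest-neighbor (default factor 5, used before 3-D rendering of
flattened nuclei) and divides the z voxel size accordingly, so physical
extent is preserved and total intensity scales exactly by the factor.

## Motif scanning

The scanner reports every window of the sequence within Hamming distance
`max_mismatch` of the pattern (default LLTPPG, `max_mismatch=0`),
left-to-right, overlaps allowed, 0-based half-open coordinates. Exact
matching is the default because the biological alignment evidence shows
extended homology but states no degeneracy rules; substitution-only fuzzy
matching is opt-in and insertions/deletions are out of scope. Input is
case-insensitive and normalized to uppercase; non-amino-acid symbols are
rejected by name. A panel classification is simply "≥1 hit", ordered as
input.

## Enrichment scoring

The network score is `-log10 P(X ≥ k)` for X hypergeometric(N, K, n): N
molecules in total, K in the network, n in the data set, k
network-eligible. The tail is inclusive of k (right-tailed Fisher exact
convention) and is accumulated as `logsumexp` over gamma-function
evaluations of the log-pmf, because the scores of interest (40+,
p ≈ 1e-41) are hopeless for naive summation of products of binomials.
`log10_right_tail` is exact for arbitrarily small tails; the `p_value`
field of a `ScoreResult` underflows to 0.0 below ~1e-308 while the score
remains correct — consumers needing the probability at that magnitude
should use the log form. The tail is clipped at 1 to absorb last-ulp
rounding at the support's lower edge. Venn partitioning treats transcript
IDs as opaque strings; probe-to-gene collapsing is out of scope.

## Synthetic data

`gen_trace` renders `baseline + A·exp(-(t-t0)²/2σ²)` on a uniform grid
plus iid Gaussian noise, clipped at zero (intensities are non-negative).
Defaults: 600 s gradient sampled at 1 Hz, peak σ = 8 s, apex 1.3e6, noise
sd 1e4 (~1% of apex). At this sampling the apex estimator's extreme-value
bias is ≈0.25% (≈2.4% mean relative error on a four-apex normalized fold
at 2% noise, 100-seed Monte-Carlo) — the apex-over-max estimator is biased
upward by construction, and a denser grid or higher noise would grow that
bias; the defaults keep it well inside the tested 1%/5% envelopes.

`gen_stack` renders hard-edged axis-aligned ellipsoidal nuclei (the
simplest shape with an unambiguous ground-truth mask) placed fully inside
the field without overlap (bounded rejection sampling; failure raises with
a diagnostic), each wrapped in an ellipsoidal cytoplasmic envelope.
Defaults describe a field of 5 flattened adherent-cell nuclei: 32×96×96
voxels at 0.041 µm (z) × 0.232 µm (xy), nuclear semi-axes 0.63/2.5/2.5 µm,
cytoplasm 1.8× wider in xy, nuclear channel 200 over background 10, blur
σ = 1 voxel, noise sd 10. The stack is sized around the nuclei, as
confocal acquisitions of nuclear translocation are. Because Gaussian blur
moves intensity across the nuclear boundary asymmetrically whenever
nucleus and cytoplasm differ in brightness, the generator calibrates the
cytoplasmic level against the *blurred* region indicators so that the
rendered pre-noise signal places exactly the requested fraction inside the
truth mask (the returned `realized_fraction` recomputes this; it matches
the request to machine precision). Requests the blur cannot realize — e.g.
a fraction of 1.0 with nonzero blur, since blur necessarily carries signal
outside the mask — raise with a diagnostic. Zero-clipped noise adds a
small positive floor (~0.4·sd per empty voxel) to the total-signal
denominator, which biases recovered fractions slightly low (≈-0.02 at a
planted 0.5, negligible below 0.3); this mimics a camera noise floor and
is left in deliberately.

What the generators do not emulate: isotope envelopes and fragmentation
(traces are single Gaussians), optical point-spread functions beyond
isotropic Gaussian blur, depth-dependent attenuation, nucleus-to-nucleus
brightness variation, touching nuclei, and compositional sequence bias in
proteins (uniform residue usage). Passing recovery tests therefore show
the pipeline is correct and unbiased under these idealized conditions, not
that it is robust to every real-world artifact — in particular the η guard
threshold and Otsu itself would need re-examination on strongly attenuated
or very low-SNR stacks.

`gen_proteins` plants the motif at known 0-based positions and
rejection-samples non-planted sequences until motif-free, making the
positive count exact; a construction check re-scans every record before
returning. `gen_expression_sets` draws `|A∪B|` distinct IDs from the
universe and splits them to make the cardinalities exact.
`gen_psm_table` assigns each row's pass/fail label first and then draws
scores/ion counts from the corresponding side of the thresholds, so filter
tests have construction-known truth (`true_pass` column). Every generator
takes an explicit seed and is bit-reproducible; there is no global random
state.

## Pipeline and reproducibility

`run_pipeline` executes the selected stages from one config mapping and a
single master seed; per-stage seeds are derived arithmetically from it, so
identical config + seed gives byte-identical summaries. Every summary and
CSV names the SHA-256 config hash (first 16 hex digits) and seed. The demo
config plants an MS fold of 3.13 and an imaging fraction pair 0.10/0.31 so
the two independent fold estimates can be cross-checked (they agree to
~2%). The msquant/imgquant pipeline stages currently run in simulate mode;
measured data go through the library functions or the `msquant`/`imgquant`
CLI subcommands, which accept CSV traces, PSM tables and TIFF manifests.

## Problem sizes

The acceptance script and the stochastic tests use 25 stacks (or stack
pairs) of 32×96×96 voxels and Monte-Carlo ensembles of 100–1000 traces;
across seeds the reported means vary by well under 1% of their values, so
these ensemble sizes characterize the estimators' bias comfortably.

## Known limitations

- Pixel-count mode's signal-positive threshold is a genuine free parameter
  (the reference description does not state one); intensity mode is the
  default and the two can disagree on blurred data.
- The apex estimator is upward-biased in noise by construction; at high
  noise or dense sampling, peak areas (provided) are preferable.
- The hypergeometric score model assumes a well-defined universe size N;
  the score is sensitive to that choice, which is the caller's.
- Hamming-only motif matching cannot express indels or position-specific
  chemistry (e.g. requiring the phospho-acceptor threonine to align).
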