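# Methods

## Decay model and fitting

Each species' abundance after transcription-initiation arrest is modelled
as a delayed exponential with a stable baseline,

    N(t) = Nf + N0,                     t ≤ α
    N(t) = Nf + N0 exp(−k (t − α)),     t > α,

continuous at t = α.  The delay α absorbs the elongation run-off period
(rifampicin blocks initiation, not elongation), so genes far from their
promoter — e.g. distal cistrons of long operons — have larger α.  Nf
captures a degradation-resistant fraction.  More elaborate run-off models
soften the breakpoint with linear or quadratic pieces; these are out of
scope here, and the sharp-breakpoint model is what is fitted.

**Objective.**  Ordinary least squares on ln N against the ln of the
measured abundances.  Log-space fitting weights all time points equally on
the relative scale, which matters because abundances span orders of
magnitude within a curve.  Zero abundances are dropped before the log
transform rather than pseudocounted (a pseudocount biases Nf); a curve
must retain at least 4 usable points (3 for the fixed-delay model).

**Optimisation.**  The objective is smooth in (N0, Nf, k) but only
piecewise smooth in α (the breakpoint crosses sample times), so α is
profiled: for each candidate delay — the sample times and their midpoints,
restricted to delays leaving ≥ 3 decaying points — the three remaining
parameters are fitted with `scipy.optimize.least_squares` (bounds
N0 ≥ 0, Nf ≥ 0, k ∈ [1e−4, 1e2] 1/min, two to three starts including a
negligible-baseline start), and the best candidate's bracket is refined by
bounded scalar minimisation of the profiled residual sum of squares.
Initial values: Nf ← min abundance, N0 ← max − min, k ← log-linear
regression slope over the decaying points.  On noiseless model data the
fit recovers all four parameters to better than 1e−3 relative error
whenever k (t_last − α) ≥ 1 (verified in the test suite to ~1e−9).

**Uncertainty.**  The 95% CI on k comes from the linearised covariance at
the optimum — s² (JᵀJ)⁻¹ with s² the residual variance on n − p degrees of
freedom — using a t quantile.  For the delayed model the Jacobian is taken
numerically in all four parameters (one-sided in α at its bounds).  A
numerically singular information matrix (condition number > 1e12, e.g. a
flat curve) marks the fit unconverged with an infinite CI, which the
reporting filter then rejects.  The rate error is defined as one quarter
of the CI width.

**Reporting filter.**  A half-life is reported iff (checked in this
order): rate error < k/2 (strict inequality — boundary equality fails),
τ = ln2/k ≤ 20 min (the final time point; slower decays are not
constrained by the sampled window), and the fit converged.  With two
biological replicates, both passing → the mean of the two half-lives
(flag "both"); exactly one passing → that value flagged "single" so
downstream consumers can include or exclude it; neither → absent.

**Fusion (baseline-exponential) model.**  Barcoded fusion libraries are
sequenced at the signal-peptide region immediately downstream of the
promoter, so the run-off delay is negligible and α is held at 0 (three
free parameters, same CI and filter machinery).  When data truly contain a
delay, this model biases k low — the flat early points dilute the decay —
a direction verified by simulation in the tests.

## Calibration

Initial: per-sample factor = arithmetic mean over spike-ins of
(known copies per cell)/(observed counts); geometric mean available.
Final: per-time-point factor target/stable_RNA(t), pinning the stable RNA
(default tmRNA at 597 copies per cell, both configurable) exactly.  Both
stages are per-sample scalar multiplications, so within-sample ratios
between species are preserved exactly, and the calibrated stable-RNA row
is constant to machine precision (it is assigned the target directly after
scaling to guard against floating-point drift).  Gene counts from read
intervals use 1-based inclusive spans, any-overlap counting, reads
overlapping several genes counted for each, and strand-aware matching by
default (directional library prep).

## Group statistics

Half-lives are grouped by the predicted location of the encoded protein;
the four analysed groups are cytoplasm, inner membrane, periplasm and
outer membrane (extracellular/unknown are excluded).  Distributions are
compared pairwise with the two-sided two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`), using the exact permutation distribution when
n·m ≤ 10⁴ and the asymptotic form otherwise; the tests cross-check the
exact p against an independent exhaustive-enumeration oracle for all
n + m ≤ 8.  KS is applied to half-lives on the natural scale; since the
statistic is invariant under monotone transforms, a log option gives
identical results.  Summary displays use mean ± SEM (sd/√n).  Replicate
concordance is the Pearson correlation of log10 values on shared,
positive species (≥ 3 required).  Signal-sequence composition analysis
bins per-sequence nucleotide counts in 3-count increments (bins 1–3, 4–6,
…), reports mean half-life ± SEM per bin, and forms cross-class ratio
curves on matched bins.

## Fusion-library design

Classification from external predictor outputs (transmembrane-span,
signal-peptide and localization predictions are *inputs*; the predictors
themselves are not reimplemented): SRP = more than one TM span AND
inner-membrane location; SecB = signal-peptide positive AND fewer than two
TM spans (N-terminal TMs misread as signal peptides are removed);
cytoplasmic controls are drawn (seeded, without replacement) from
cytoplasmic proteins in neither class.  The 30-aa window is centered on
the midpoint of the first TM span for SRP (window [center−14, center+15],
clamped to residues 1–30 at the N-terminus; C-terminal overflow — not an
issue for genuine membrane proteins — is clamped to the last 30 residues
with a warning), and residues 1–30 for SecB/controls.  Windows that do
not begin with ATG keep their native first codon; no start codon is
prepended.  Encodings: native CDS substring; synthetic — each codon
replaced by a synonymous codon drawn with genome codon-usage weights
(embedded E. coli K-12 table, replaceable); untranslated — first two
codons replaced by TAA TAA.  The linker is fixed to GGT GGA TCA GGA GGT
TCA (GGSGGS; only the amino acids are externally constrained).  The
90-nt signal region is the amplified/sequenced region and therefore the
barcode; barcodes are unique among signal-peptide variants, each
test-gene pool is counted separately, and reads are matched by exact
90-mer lookup scanned over leading random-offset prefixes of 0–8 nt.

## Probe design

Template = I1 | RTP | Nb.BsmI site | rc(TR) | rc(Nb.BsrDI site) | I2, with
RTP = CAGGCATCCGAGAGGTCTGG; nick-site sequences default to GAATGC/GCAATG
and are configurable.  Targeting regions are 30-nt, GC 50–60%, duplex Tm
80–85 °C, non-overlapping within a transcript, greedy left-to-right.
Melting temperatures use Biopython nearest-neighbour thermodynamics
(DNA_NN4) reported at the 1 M Na⁺ convention of oligo-design tools; at the
hybridization-buffer salt (~0.3 M Na⁺ with formamide) the same oligos melt
~15 °C lower, so the windows are meaningful only together with their
declared reporting condition — salt and formamide corrections are
parameters, and the windows are configurable.  Cross-hybridization is
screened as any shared exact ≥16-nt substring (either strand) with any
other transcript or previously accepted region — a deliberately
conservative proxy for a 75 °C hybridization-free-energy screen, threshold
configurable.  Index primers: candidates truncated to 20 nt; Tm 65–70 °C,
GC 50–60%, no run of ≥ 4 identical bases, 3′ clamp of 2–3 G/C in the final
five bases, and no shared ≥12-nt substring with the transcriptome, the T7
promoter, the RTP, or previously accepted primers.  Transcriptome
partitioning: location × abundance range with half-open ranges [1/3, 3),
[3, 30), [30, 300) copies per cell (a gene at exactly 3 falls in 3–30);
genes outside all ranges are collected as "unexpressed"; cytoplasmic
genes keep a seeded random third of their targeting regions; alternating
100-kb genomic windows (the 2nd, 4th, … window) assign genes by start
coordinate; an optional split separates genes sharing an operon with an
inner-membrane cistron.

## Cell geometry

Boundaries are extracted as the iso-intensity contour maximising the mean
gradient magnitude along itself (two-stage level scan, sub-pixel via
marching squares); contrast inversion is handled by a flag.  The boundary
is resampled to 400 equal-arc vertices and Gaussian-smoothed (σ = 2
vertices) before finite-difference curvature estimation; poles are the two
curvature maxima separated by ≥ 25% of the perimeter, each refined to the
midpoint of its contiguous high-curvature run (a spherocylinder cap has
constant curvature, so the raw argmax is arbitrary within the cap).  A
boundary whose curvature maxima do not exceed 1.5× the median is rejected
as degenerate (near-circular).  Each side between the poles is divided
into 100 equal-arc regions; corresponding division points are joined into
ribs (the two end ribs are degenerate at the poles), and the 101 rib
midpoints form the centerline.  QC: side lengths within 20% of each other
(max/min ≤ 1.2, equality passes) and area ≤ 3 µm².

Localizations map to X = arc fraction of the nearest centerline point,
Y = signed in-plane offset / local rib half-length, Z = axial offset /
the same half-length (circular cross-section assumption).  |Y| > 1.2 is
flagged, not dropped — localization error straddles the membrane, which is
exactly where the signal of interest lies.  Density profiles histogram Y
over |Z| ≤ 0.5 and X ∈ [0.1, 0.9]; for a uniform cylinder the analytic
reference is c(Y) ∝ min(0.5, √(1−Y²)).  The membrane enrichment index is
the mean density over 0.75 ≤ |Y| ≤ 1 divided by the mean over |Y| ≤ 0.5
(+∞ for a pure shell).  Average cross-sections are 2-D histograms with the
slab axis exposed as configuration (physical 150-nm slices are converted
to normalized units per cell by its mean rib half-length upstream).  On
bent cells the rib construction recovers the true arc over the central
half of the centerline; the cap-adjacent ends are systematically distorted
(rib pairing inside the caps), so curvature measurements should use the
interior, as the tests do.

## Synthetic data

The generators emulate the statistical structure each stage assumes, at
the study's conditions: 8 time points at 0, 1, 2, 4, 6, 9, 14, 20 min
(the end points are fixed by the assay; the interior grid is a free
choice), per-parameter uniform sampling with defaults N0 ∈ [500, 5000]
(counting-noise-dominated but well-measured t = 0 levels), Nf ∈ [5, 50],
half-lives 1–15 min, delays 0–5 min, four constant spike-ins spanning
100–3000 copies per cell, Poisson counting noise on expected copies ×
per-sample depth factor (negative-binomial overdispersion is not
modelled).  Cells are spherocylinders (length 3.0 ± 0.3 µm, width
1.00 ± 0.05 µm), optionally mapped through a constant-curvature arc;
membrane-shell points are area-weighted over cylinder and caps,
uniform-volume points volume-weighted, nucleoid depletion is a coaxial
exclusion cylinder (0.6 R over the central 60% of length).  The toy
proteome assigns locations by configurable fractions, gives
inner-membrane proteins 2–4 hydrophobic TM spans and exported proteins a
positive signal-peptide flag, and encodes CDSs by codon-usage sampling.

What passing tests do *not* show about real data: no optics/PSF or camera
noise, no drift, no multi-cell segmentation, no sequence-composition
biases in counting, no rRNA contamination, and predictor outputs are
generated, not predicted — so the pipeline's robustness to real predictor
errors and real imaging artefacts is untested by construction.

## Determinism and numerics

Every stochastic generator takes an explicit seed
(`numpy.random.default_rng`) and is byte-reproducible.  Fits are
deterministic given identical input.  Tolerances used in the tests:
1e−3 relative for noiseless parameter recovery, sup-norm 0.05 for the
1e5-point uniform profile, exact equality for calibration pinning and QC
thresholds.
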