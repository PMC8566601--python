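# Methods

This note documents the models implemented by `cardiosplice`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Coordinates and transcript regions

All intervals are 0-based half-open internally (the BED convention; two
intervals overlap iff `a.start < b.end and b.start < a.end`, so abutting
intervals do not overlap). GTF input is converted on read from 1-based
inclusive coordinates. A transcript's CDS span is the envelope
(min start .. max end) of its CDS records; only the envelope endpoints
must fall inside exons.

`derive_regions` partitions each transcript body exactly — every base
between the first exon start and last exon end receives exactly one
category. Exonic bases coordinate-left of the CDS are the 5′UTR on the
plus strand and the 3′UTR on the minus strand (roles swap with strand);
intronic bases within **500 nt** of either flanking splice site are
proximal intron, the remainder distal. The 500 nt threshold follows the
convention of the standard CLIP peak-annotation tools; it is a
parameter (`proximal_nt`) everywhere it matters. Introns shorter than
1,000 nt are therefore entirely proximal. A "3′ ends" category used by
some annotation pipelines is not implemented separately; 3′-end-adjacent
bases fall into the 3′UTR or intron categories.

Genes with several transcripts are reduced to one representative:
longest CDS, ties broken by transcript length, then lexicographic
transcript id. Downstream peak annotation sees one region set per gene.

## Peak annotation and profiles

A peak is assigned to the gene with the largest base overlap
(alphabetical gene id on ties) and, within that gene, to the category
covering the majority of its bases. Category ties break in the order
3′UTR > 5′UTR > CDS exon > noncoding exon > proximal intron > distal
intron — UTR localization is the phenotype of interest, so UTR
categories win. Annotation is strand-aware when both peak and region
strands are known; the plain interval `intersect` is strand-blind by
default, matching `bedtools intersect`. Peaks with no gene overlap are
`intergenic` and are excluded from the frequency-profile denominator.

Profile similarity is Pearson correlation of frequency vectors over the
fixed category set (the correlation type is configurable in principle;
Pearson on frequencies is the default and what the tests pin down).
Zero-variance profiles have undefined correlation and rank last.
Overlap similarity is the percentage of query peaks touched by ≥1
reference peak, which makes the ranking invariant to splitting a
reference peak into abutting halves.

Motif density counts overlap-allowed occurrences of the
DNA-transcribed motif (U≡T) on the annotated strand, per kb of peak
sequence. Enrichment over a background peak set is tested with a
one-sided binomial test of the peak occurrence count against the
background per-position rate. De novo motif discovery is out of scope;
the scorer is intended for a known consensus such as UCUU.

## PSI and the moderated test

PSI per sample is `incl / (incl + excl)`, missing below a
`min_total_reads` depth of 10. Differential-event filtering requires
detection in ≥75% of each compared group's samples and |group-mean
δPSI| > 0.1 (strict inequality).

The moderated t-test fits, per event, ordinary least squares of PSI on
an intercept, the contrast column, and fixed-effect batch indicator
columns. With residual variance s² on d degrees of freedom, variances
are shrunk toward a prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),
    t̃ = β / (se_unit · s̃),  p from t on d₀ + d df,

where se_unit is the unscaled standard error of the contrast
coefficient. The prior (d₀, s₀²) comes from the method of moments on
log residual variances: with e = log s² − ψ(d/2) + log(d/2), the excess
of var(e) over the mean of ψ′(d/2) identifies ψ′(d₀/2), inverted by
Newton iteration; s₀² is then exp(mean(e) + ψ(d₀/2) − log(d₀/2)). d₀ is
capped at 10⁶ ("effectively pooled"). When the log variances show *no*
excess spread (evar ≤ 0) the prior collapses onto the geometric mean of
the observed s², so that identical residual variances shrink to
themselves and the moderated t reduces exactly to the ordinary t; the
bias-corrected back-transform used on the main branch would instead
inflate the prior by exp(log(d/2) − ψ(d/2)) (≈7.6% at d = 14), which is
appropriate for chi-square sampling spread but not for the degenerate
case. Benjamini–Hochberg correction is applied across events, per
contrast.

Batch enters all models as a fixed covariate. At these group sizes
(4 samples per genotype, 2 batches balanced across genotypes) a random
batch intercept and a fixed one give the same contrast estimates; a
random-effect structure is not implemented.

## Genotype models and patterns

Four contrasts are fitted per event: (1) HTZ vs all others, (2) HMZ vs
all others, (3) HTZ+HMZ vs WT (KO excluded), (4) allele dose 0/1/2 over
WT/HTZ/HMZ (KO excluded). The best model is the smallest raw p, ties
broken toward the more constrained dosage interpretation (4 > 3 > 2 >
1). An event is called when the best model's BH-adjusted p < 0.1 and
its |δPSI| > 0.1, where δPSI is the fitted extreme-group difference
(twice the per-allele slope for the dose model). KO-specific events
have no dedicated model among the four and are expected to surface in
pattern assignment instead.

Pattern assignment correlates each event's PSI vector with the 0/1
indicator of every group across several sample groupings — the primary
genotypes, an aggregated R636S group (HTZ+HMZ), and an any-mutation
group (HTZ+HMZ+KO) — and assigns the (grouping, group) with maximal
Pearson correlation among templates whose correlation-test p < 0.05.
Groups with fewer than two samples are skipped. A monotone
allele-dose profile correlates almost equally with the HMZ indicator
(r ≈ 0.87 at these group sizes) and the aggregated R636S indicator
(r ≈ 0.90), so dosage-additive events legitimately land on either; both
are counted as correct in the recovery tests.

APA ratios are isoform abundance over the per-gene total, per sample
(missing when the total is zero). circRNA records are kept at ≥2 total
back-splice reads. Upper-quartile normalization scales each sample by
the 75th percentile of its nonzero counts, re-centered by the geometric
mean of the factors so the overall scale is preserved; differential
circRNA testing itself (NB-GLM) is out of scope.

## Contractility

Post stiffness is the end-loaded cantilever closed form k = 3EI/L³,
I = πd⁴/64, with the full 12.5 mm post as the lever arm; at E = 2.5 MPa
(PDMS) and d = 1.5 mm this gives 0.954 N/m ≡ 0.954 µN/µm, matching the
0.95 µN/µm figure used for these posts. Whether a cap correction
shortens the effective lever arm is an open question; the uncorrected
form reproduces the standard value.

Post tracking thresholds each frame with Otsu's method (computed over
the whole stack), labels connected components, takes the two largest as
posts, and measures the distance between intensity-weighted centroids
(sub-pixel). The resting baseline is the maximum of the
Savitzky–Golay-smoothed (window 7, order 3) separation trace —
contraction can only pull the posts together. Deflection is baseline
minus separation, converted at 8.3 µm/px; force is k·Δ(t).

Twitch metrics segment the force trace into pacing periods (2 Hz
default). Peak force per beat is the smoothed-trace maximum above the
window minimum; dF/dt extremes come from the Savitzky–Golay derivative
(window 7, order 3 at 66 fps, configurable); RT50/RT90 are times from
peak to 50%/90% relaxation. Reported values are per-beat means over the
first `n_beats` (default 10) complete beats. Peak extraction uses the
smoothed trace because a raw per-frame maximum rides on the centroid
jitter extreme and is biased upward under pixel noise.

FPDc applies Fridericia's correction FPD/(period)^⅓ per beat, keeping
per electrode the 30 beats with the smallest absolute deviation of beat
period from the electrode median (a concrete stability criterion; the
original instrument software leaves it operator-dependent), then
averages per electrode and across electrodes (mean of means).

## Localization

Nuclear percentage is 100 × Σ signal inside the nuclear mask / Σ total
signal (intensity-weighted; voxel-count mode available), so nuclear +
cytoplasmic = 100 exactly and the measure is invariant to uniform
intensity scaling. Co-localization is the Pearson correlation of voxel
intensities, optionally after max-intensity projection along z
(default off for fractions, on in the CLI co-localization command,
matching the segment-then-project workflow). Segmentation itself is
upstream and out of scope.

## Synthetic data: what it does and does not emulate

A single global seed fans out through `numpy.random.SeedSequence` spawn
keys, one fixed key per stage, so stages regenerate independently and
byte-identically.

- **Toy transcriptome**: 2–8 exons per gene, exons 150–400 nt, introns
  200–2,500 nt (spanning the proximal/distal boundary), UTRs ≥100 nt,
  uniform-random sequence on one chromosome. Real exome structure,
  GC content, and overlapping genes are not modelled.
- **Peaks**: fixed 50 nt width, placed uniformly within a
  length-weighted region of a category drawn from the requested
  distribution; motifs are planted on the transcript strand with a
  given probability. Crosslink-site geometry and peak-width variation
  are not modelled, so near-perfect annotation accuracy on synthetic
  peaks bounds only the interval logic, not real-data accuracy.
- **Junction counts**: totals Poisson(depth = 200 by default),
  inclusion Binomial(total, p) with p = genotype-truth PSI ±0.02 per
  differentiation batch plus N(0, 0.02) per-sample noise. Pattern
  effect size defaults to δPSI = 0.3 over a 0.5 baseline, with the
  dosage-additive pattern applying half the effect in HTZ. The standard
  design is 4 samples per genotype in 2 balanced batches. Overdispersed
  read counts and correlated events are not modelled.
- **Twitch videos**: two soft-edged discs at 66 fps and 8.3 µm/px,
  baseline post separation 750 µm; the flexible post follows
  F(t) ∝ (1 − e^(−t/τ_r))·e^(−t/τ_d) tiled at the pacing frequency and
  normalized so its analytic peak equals the requested deflection.
  τ_r = 0.07 s and τ_d = 0.12 s give a ~70 ms time-to-peak and ~97%
  relaxation within a 500 ms pacing cycle, representative of 2 Hz-paced
  engineered-heart-tissue twitches; a waveform that does not return
  near baseline within the cycle would confound any baseline estimated
  from the trace itself. Pixel noise is additive Gaussian. Optics
  (blur, illumination drift) and out-of-plane motion are not modelled.
- **MEA tables**: per-electrode, per-beat period and FPD with Gaussian
  jitter; no raw voltage traces or T-wave morphology.
- **Volumes**: a central ellipsoidal nuclear mask and single-voxel
  puncta inside and outside, with inside intensities rescaled so the
  nuclear share of total signal equals the requested fraction exactly.
  No PSF, no boundary-straddling particles.

Problem sizes used by the test suite and the acceptance script (50
genes, 2,000 peaks, 160 events × 16 samples at depth 200, 363-frame
videos, 10 seeds) were chosen so every stochastic check has comfortable
statistical margin while the whole suite runs in seconds.

## Known limitations

- Cassette-exon events only; intron retention and alternative-promoter
  events are not modelled, and multi-junction inclusion counts are
  averaged (configurable to sum) rather than modelled jointly.
- The moderated test treats PSI as Gaussian; at extreme PSI or very low
  depth a binomial GLM would be more faithful.
- Pattern assignment uses positive correlation with 0/1 indicators, so
  exon-exclusion events assign to the group where inclusion is *high*;
  direction is recovered from the sign of δPSI, not the assignment.
- Tracking assumes exactly two posts resolvable in every frame and
  one-dimensional bending; it reports deflection magnitude, not
  direction.
- Liftover, GFF3 dialects, peak calling, motif discovery, circRNA
  discovery from alignments, and enrichment analyses are all upstream
  or downstream of this package by design.
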