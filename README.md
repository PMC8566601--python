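# cardiosplice

Analysis pipeline for the multi-omics readouts used to characterize
RBM20 cardiomyopathy mutations (e.g., R636S) in iPSC-derived
cardiomyocytes, built to run end-to-end on synthetic data with known
ground truth.

RBM20 is a cardiac splicing regulator; dilated-cardiomyopathy missense
mutations in its RS domain mislocalize the protein from the nucleus to
the cytoplasm, where it shifts its RNA binding from intronic UCUU
elements near regulated exons into 3′UTRs. Characterizing that shift —
and its downstream consequences on splicing, contractility, and
electrophysiology — requires a set of bespoke computations that this
package implements as a tested library:

- **Genomic regions** (`cardiosplice.intervals`): 0-based half-open
  interval arithmetic, GTF/BED I/O, and partition of transcript bodies
  into 5′UTR / CDS exon / proximal intron (≤500 nt from a splice site) /
  distal intron / 3′UTR categories.
- **eCLIP profiles** (`cardiosplice.eclip`): majority-base peak
  annotation, region-frequency profiles, RBP similarity ranking by
  Pearson profile correlation and by percent peak overlap, and
  UCUU-motif density with a binomial enrichment test.
- **Splicing inference** (`cardiosplice.splicing`): percent spliced-in
  (PSI) from inclusion/exclusion junction counts,
  PSI = incl / (incl + excl); event filtering (detected in ≥75% of each
  group's samples, |δPSI| > 0.1); empirical-Bayes moderated t-tests
  with variance shrinkage s̃² = (d₀s₀² + d·s²)/(d₀ + d), the prior
  (d₀, s₀²) estimated by method of moments on log residual variances;
  four genotype models (HTZ-specific, HMZ-specific, shared HTZ+HMZ vs
  WT, additive allele dose 0/1/2); MarkerFinder-style pattern
  assignment by correlation to idealized group indicators; 3′UTR
  isoform (APA) ratios; circRNA read filtering and upper-quartile
  normalization.
- **Coordinate integration** (`cardiosplice.integrate`): joins of peaks
  and circRNA back-splice spans against splicing events (alternative
  exon + flanking introns).
- **Contractility & MEA** (`cardiosplice.contractility`): cantilever
  post stiffness k = 3EI/L³ with I = πd⁴/64 (E = 2.5 MPa, d = 1.5 mm,
  L = 12.5 mm → k = 0.95 µN/µm); centroid tracking of the flexible
  post in twitch videos; F(t) = k·Δ(t); per-beat twitch kinetics; and
  Fridericia-corrected field potential duration
  FPDc = FPD / (beat period)^⅓ over the 30 most stable beats.
- **Localization** (`cardiosplice.localization`): intensity-weighted
  nuclear/cytoplasmic signal percentages from 3D masks and Pearson
  voxel co-localization.
- **Synthetic data** (`cardiosplice.synthetic`): deterministic
  generators for every input above, each emitting a machine-readable
  truth table.

## Worked example

```python
import cardiosplice as cs

# 1. micropost stiffness from beam theory
k = cs.post_stiffness(cs.PostGeometry())      # 0.9543 uN/um

# 2. mutant-like eCLIP peaks over a toy transcriptome
gtf, fasta = cs.make_toy_transcriptome(50, seed=42, out_dir="scratch")
bed, truth, fa = cs.simulate_peaks(
    gtf, fasta,
    {"three_prime_utr": 0.75, "distal_intron": 0.10,
     "proximal_intron": 0.05, "cds_exon": 0.05, "five_prime_utr": 0.05},
    n_peaks=2000, seed=42)
models = cs.representative_transcripts(cs.read_gtf(gtf))
regions = [r for m in models for r in cs.derive_regions(m)]
labels = cs.annotate_peaks(cs.PeakSet("mutant", tuple(cs.read_bed(bed))), regions)
profile = cs.region_profile(labels, "mutant")
print(profile.frequencies["three_prime_utr"])  # 0.7545

# 3. genotype-pattern splicing inference
design = cs.make_design()                      # 4 samples x WT/HTZ/HMZ/KO
truths = cs.make_splicing_truths(dpsi=0.3)     # 6 patterns + null events
jc = cs.simulate_junction_counts(design, truths, depth=200, seed=3)
fits = cs.fit_genotype_models(cs.compute_psi(jc), design)
print(fits.loc["ev0001_dosage_additive"].to_string())
# best_model     dosage_additive
# p_raw                      0.0
# p_fdr                 0.000007
# dpsi                  0.331181
# significant               True
```

The stiffness (0.9543 µN/µm at the standard post geometry) converts
tracked deflection to force; the 3′UTR frequency (75.5% of 2,000 peaks
placed with probability 0.75) shows the annotation stage recovering a
mutant-like binding distribution; the model fit assigns a simulated
dosage-additive event (PSI 0.5/0.65/0.8 over 0/1/2 mutant alleles)
to the additive allele-dose model with fitted δPSI 0.33 at FDR ≪ 0.1.

The same stages are scriptable from the shell:

```sh
cardiosplice simulate peaks --seed 42 --out d
cardiosplice eclip profile --bed d/peaks.bed --gtf d/toy.gtf --label mutant --out prof.tsv
cardiosplice simulate junctions --seed 1 --out j
cardiosplice splicing models --counts j/junction_counts.tsv --design j/design.tsv --out models.tsv
cardiosplice mea fpdc --beats beats.tsv
```

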