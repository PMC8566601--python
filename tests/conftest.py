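import pathlib

import pytest

import cardiosplice as cs

MUTANT_PROBS = {
    "three_prime_utr": 0.75,
    "distal_intron": 0.10,
    "proximal_intron": 0.05,
    "cds_exon": 0.05,
    "five_prime_utr": 0.05,
}


@pytest.fixture(scope="session")
def toy_transcriptome(tmp_path_factory) -> tuple[pathlib.Path, pathlib.Path]:
    """50-gene toy GTF + FASTA, seed 42 (the standard peak substrate)."""
    out = tmp_path_factory.mktemp("toy50")
    return cs.make_toy_transcriptome(50, 42, out)


@pytest.fixture(scope="session")
def toy_regions(toy_transcriptome):
    gtf, _ = toy_transcriptome
    models = cs.representative_transcripts(cs.read_gtf(gtf))
    return [r for m in models for r in cs.derive_regions(m)]


@pytest.fixture(scope="session")
def mutant_peaks(toy_transcriptome, tmp_path_factory):
    """2000 peaks with the mutant-like 3'UTR-dominated placement, seed 42."""
    gtf, fasta = toy_transcriptome
    out = tmp_path_factory.mktemp("peaks")
    bed, truth, fa = cs.simulate_peaks(
        gtf, fasta, MUTANT_PROBS, n_peaks=2000, seed=42, motif="TCTT",
        motif_rate=0.0, out_dir=out,
    )
    return bed, truth, fa


@pytest.fixture(scope="session")
def design():
    return cs.make_design(n_per_genotype=4, n_batches=2)


@pytest.fixture(scope="session")
def standard_junctions(design):
    """Standard synthetic splicing design: 6 patterns + nulls, depth 200."""
    truths = cs.make_splicing_truths(n_per_pattern=20, n_null=40, dpsi=0.3, direction="up")
    jc = cs.simulate_junction_counts(design, truths, depth=200, seed=3)
    return jc, truths
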