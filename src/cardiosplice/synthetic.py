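"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic given its seed. A single global seed
fans out to per-stage child seeds through ``numpy.random.SeedSequence``
spawn keys (one fixed key per stage, see ``_STAGE_KEYS``), so any stage
can be regenerated independently of the others.

The generators emulate the study conditions of an RBM20 R636S
iPSC-cardiomyocyte experiment: eCLIP peak sets with a controllable
region-placement distribution (the mutant protein binds predominantly
in 3'UTRs, the wild type in introns) and UCUU motif planting; splice
junction counts realizing six genotype patterns over WT/HTZ/HMZ/KO
samples; twitch videos of a rigid and a flexible micropost at 66 fps
and 8.3 um/px; multi-electrode beat tables with a known field-potential
duration; and 3D volumes with a known nuclear/cytoplasmic signal split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CATEGORIES,
    GenomicInterval,
    TranscriptModel,
    derive_regions,
    representative_transcripts,
    read_gtf,
    write_gtf,
)

_STAGE_KEYS = {
    "transcriptome": 0,
    "peaks": 1,
    "junctions": 2,
    "twitch": 3,
    "mea": 4,
    "volume": 5,
}

GENOTYPES = ("WT", "HTZ", "HMZ", "KO")

#: PSI offset applied to the affected genotype(s) of each pattern,
#: relative to a baseline PSI. 0.3 gives clearly differential events
#: (|dPSI| three times the retention threshold) at realistic depth.
PATTERN_GENOTYPES: dict[str, tuple[str, ...]] = {
    "dosage_additive": ("HTZ", "HMZ"),  # half effect in HTZ, full in HMZ
    "dosage_independent_r636s": ("HTZ", "HMZ"),
    "htz_specific": ("HTZ",),
    "hmz_specific": ("HMZ",),
    "ko_specific": ("KO",),
    "shared_all": ("HTZ", "HMZ", "KO"),
    "null": (),
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child RNG for a named stage, derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    )


# ---------------------------------------------------------------------------
# toy transcriptome


def make_toy_transcriptome(
    n_genes: int, seed: int, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a deterministic toy GTF + FASTA with ``n_genes`` coding genes.

    Each gene has 2-8 exons, a CDS, and UTRs of at least 100 nt; intron
    lengths span the proximal/distal boundary so all region categories
    exist. Sequence is uniform-random ACGT. Returns (gtf_path, fasta_path).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = stage_rng(seed, "transcriptome")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    models: list[TranscriptModel] = []
    pos = 1000
    for g in range(n_genes):
        n_exons = int(rng.integers(2, 9))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(200, 2501, size=max(0, n_exons - 1))
        exons = []
        cur = pos
        for i in range(n_exons):
            exons.append(GenomicInterval("chr1", cur, cur + int(exon_lens[i]), strand))
            cur += int(exon_lens[i])
            if i < n_exons - 1:
                cur += int(intron_lens[i])
        utr_left = int(rng.integers(100, 141))
        utr_right = int(rng.integers(100, 141))
        cds_span = GenomicInterval(
            "chr1", exons[0].start + utr_left, exons[-1].end - utr_right, strand
        )
        gid = f"GENE{g + 1:03d}"
        models.append(TranscriptModel(gid, f"{gid}.t1", strand, tuple(exons), cds_span))
        pos = cur + 800

    gtf_path = out_dir / "toy.gtf"
    write_gtf(models, gtf_path)

    chrom_len = pos + 200
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len)
    fasta_path = out_dir / "toy.fa"
    _write_fasta({"chr1": seq}, fasta_path)
    return gtf_path, fasta_path


def _write_fasta(seqs: Mapping[str, np.ndarray], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = arr.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    seqs: dict[str, np.ndarray] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = np.frombuffer("".join(chunks).encode(), dtype="S1").copy()
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = np.frombuffer("".join(chunks).encode(), dtype="S1").copy()
    return seqs


_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgtUu", "TGCAtgcaAa"))[::-1]


# ---------------------------------------------------------------------------
# eCLIP peaks


def simulate_peaks(
    gtf_path: str | Path,
    fasta_path: str | Path,
    probs: Mapping[str, float],
    n_peaks: int,
    seed: int,
    motif: str = "TCTT",
    motif_rate: float = 0.0,
    peak_width: int = 50,
    out_dir: str | Path | None = None,
) -> tuple[Path, Path, Path]:
    """Place peaks in transcript regions drawn from ``probs``.

    Each peak's category is drawn from ``probs`` (over region
    categories), then the peak is placed uniformly inside a region of
    that category (regions weighted by usable length). With probability
    ``motif_rate`` the transcribed motif is planted in the genome
    sequence under the peak, on the transcript strand. Returns paths to
    (BED6 peaks, truth TSV, FASTA with planted motifs).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not 0 <= motif_rate <= 1:
        raise ValueError("motif_rate must be in [0, 1]")
    probs = dict(probs)
    bad = set(probs) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in probs: {sorted(bad)}")
    total = sum(probs.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"region probabilities sum to {total}, expected 1")

    rng = stage_rng(seed, "peaks")
    out_dir = Path(out_dir) if out_dir is not None else Path(gtf_path).parent
    out_dir.mkdir(parents=True, exist_ok=True)

    models = representative_transcripts(read_gtf(gtf_path))
    regions_by_cat: dict[str, list] = {}
    for m in models:
        for r in derive_regions(m):
            if len(r.interval) >= peak_width:
                regions_by_cat.setdefault(r.category, []).append(r)

    cats = sorted(probs)
    pvec = np.array([probs[c] for c in cats])
    for c in cats:
        if probs[c] > 0 and c not in regions_by_cat:
            raise ValueError(
                f"no region of category {c!r} (>= peak width {peak_width}) in transcriptome"
            )

    seqs = _read_fasta(fasta_path)
    motif_dna = motif.upper().replace("U", "T").encode()

    rows, truth = [], []
    cat_draws = rng.choice(len(cats), size=n_peaks, p=pvec)
    for i, ci in enumerate(cat_draws):
        cat = cats[ci]
        regs = regions_by_cat[cat]
        weights = np.array([len(r.interval) - peak_width + 1 for r in regs], dtype=float)
        reg = regs[rng.choice(len(regs), p=weights / weights.sum())]
        start = int(rng.integers(reg.interval.start, reg.interval.end - peak_width + 1))
        iv = GenomicInterval(
            reg.interval.chrom, start, start + peak_width, reg.interval.strand,
            name=f"peak{i + 1:05d}",
        )
        planted = False
        if motif_rate > 0 and rng.random() < motif_rate:
            off = int(rng.integers(0, peak_width - len(motif_dna) + 1))
            ins = motif_dna
            if iv.strand == "-":
                ins = motif_dna.translate(_COMPLEMENT)[::-1]
            seqs[iv.chrom][start + off : start + off + len(ins)] = np.frombuffer(
                ins, dtype="S1"
            )
            planted = True
        rows.append(iv)
        truth.append(
            {
                "peak_id": iv.name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "category": cat,
                "gene_id": reg.gene_id,
                "motif_planted": int(planted),
            }
        )

    from .intervals import write_bed

    bed_path = out_dir / "peaks.bed"
    write_bed(rows, bed_path)
    truth_path = out_dir / "peaks_truth.tsv"
    pd.DataFrame(truth).to_csv(truth_path, sep="\t", index=False)
    fasta_out = out_dir / "genome_with_motifs.fa"
    _write_fasta(seqs, fasta_out)
    return bed_path, truth_path, fasta_out


# ---------------------------------------------------------------------------
# splicing


@dataclass(frozen=True)
class SplicingTruth:
    """Ground-truth PSI per genotype for one cassette-exon event."""

    event_id: str
    pattern: str
    psi: Mapping[str, float]  # genotype -> PSI in [0, 1]

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_GENOTYPES:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for g, p in self.psi.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.event_id}: PSI {p} for {g} outside [0, 1]")


def make_design(
    n_per_genotype: int = 4, n_batches: int = 2
) -> pd.DataFrame:
    """Sample sheet: WT/HTZ/HMZ/KO samples assigned round-robin to batches."""
    rows = []
    for g in GENOTYPES:
        for i in range(n_per_genotype):
            rows.append(
                {
                    "sample_id": f"{g}_{i + 1}",
                    "genotype": g,
                    "batch": f"b{i % n_batches + 1}",
                }
            )
    return pd.DataFrame(rows)


def make_splicing_truths(
    n_per_pattern: int = 20,
    n_null: int = 40,
    base_psi: float = 0.5,
    dpsi: float = 0.3,
    direction: str = "up",
) -> list[SplicingTruth]:
    """Truth table covering the six genotype patterns plus null events.

    ``direction='up'`` raises PSI in the affected genotypes by ``dpsi``
    (exon-inclusion events); ``'down'`` lowers it (exon-exclusion).
    The dosage-additive pattern applies half the effect in HTZ.
    """
    sign = {"up": 1.0, "down": -1.0}[direction]
    truths = []
    k = 0
    for pattern, affected in PATTERN_GENOTYPES.items():
        n = n_null if pattern == "null" else n_per_pattern
        for _ in range(n):
            k += 1
            psi = {g: base_psi for g in GENOTYPES}
            for g in affected:
                delta = dpsi
                if pattern == "dosage_additive" and g == "HTZ":
                    delta = dpsi / 2
                psi[g] = float(np.clip(base_psi + sign * delta, 0, 1))
            truths.append(SplicingTruth(f"ev{k:04d}_{pattern}", pattern, psi))
    return truths


@dataclass
class JunctionCounts:
    """Inclusion/exclusion junction read counts, events x samples."""

    inclusion: pd.DataFrame
    exclusion: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)  # event_id-indexed

    def __post_init__(self) -> None:
        if not self.inclusion.index.equals(self.exclusion.index) or not (
            self.inclusion.columns.equals(self.exclusion.columns)
        ):
            raise ValueError("inclusion/exclusion tables must share index and columns")
        if (self.inclusion.values < 0).any() or (self.exclusion.values < 0).any():
            raise ValueError("junction counts must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        wide = self.meta.copy() if len(self.meta) else pd.DataFrame(index=self.inclusion.index)
        for s in self.inclusion.columns:
            wide[f"{s}__incl"] = self.inclusion[s]
            wide[f"{s}__excl"] = self.exclusion[s]
        wide.to_csv(path, sep="\t", index_label="event_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JunctionCounts":
        wide = pd.read_csv(path, sep="\t", index_col="event_id")
        incl_cols = [c for c in wide.columns if c.endswith("__incl")]
        samples = [c[: -len("__incl")] for c in incl_cols]
        incl = wide[[f"{s}__incl" for s in samples]].copy()
        incl.columns = samples
        excl = wide[[f"{s}__excl" for s in samples]].copy()
        excl.columns = samples
        meta_cols = [c for c in wide.columns if not c.endswith(("__incl", "__excl"))]
        return cls(incl, excl, wide[meta_cols])


def simulate_junction_counts(
    design: pd.DataFrame,
    truths: Sequence[SplicingTruth],
    depth: int,
    seed: int,
    batch_shift: float = 0.02,
    noise_sd: float = 0.02,
) -> JunctionCounts:
    """Binomial junction counts around genotype-truth PSI.

    Per event and sample: total reads ~ Poisson(depth); inclusion reads
    ~ Binomial(total, p) with p = truth PSI for the sample's genotype,
    shifted by +/-``batch_shift`` depending on batch (emulating
    differentiation-batch effects) plus N(0, noise_sd) per-sample
    noise, clipped to [0, 1].
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = stage_rng(seed, "junctions")
    samples = design["sample_id"].tolist()
    batches = sorted(design["batch"].unique())
    shift = {b: batch_shift * (1 if i % 2 == 0 else -1) for i, b in enumerate(batches)}

    for t in truths:
        missing = set(design["genotype"]) - set(t.psi)
        if missing:
            raise ValueError(f"{t.event_id}: truth lacks genotypes {sorted(missing)}")

    incl = np.zeros((len(truths), len(samples)), dtype=int)
    excl = np.zeros_like(incl)
    for j, (_, row) in enumerate(design.iterrows()):
        for i, t in enumerate(truths):
            total = int(rng.poisson(depth))
            p = float(
                np.clip(
                    t.psi[row["genotype"]] + shift[row["batch"]] + rng.normal(0, noise_sd),
                    0,
                    1,
                )
            )
            k = int(rng.binomial(total, p)) if total > 0 else 0
            incl[i, j] = k
            excl[i, j] = total - k

    idx = pd.Index([t.event_id for t in truths], name="event_id")
    meta = pd.DataFrame(
        {"gene_id": [f"G_{t.event_id}" for t in truths], "pattern": [t.pattern for t in truths]},
        index=idx,
    )
    return JunctionCounts(
        pd.DataFrame(incl, index=idx, columns=samples),
        pd.DataFrame(excl, index=idx, columns=samples),
        meta,
    )


# ---------------------------------------------------------------------------
# twitch videos


@dataclass(frozen=True)
class TwitchTruth:
    """Known twitch kinetics used to synthesize a post-tracking video."""

    peak_deflection_um: float = 8.0
    twitch_frequency_hz: float = 2.0
    rise_tau_s: float = 0.07
    decay_tau_s: float = 0.12
    baseline_separation_um: float = 750.0

    def __post_init__(self) -> None:
        if self.peak_deflection_um < 0:
            raise ValueError("peak_deflection must be >= 0")
        if self.twitch_frequency_hz <= 0:
            raise ValueError("twitch_frequency must be > 0")


def twitch_waveform(t: np.ndarray, truth: TwitchTruth) -> np.ndarray:
    """Deflection (um) at times ``t`` for a paced twitch train.

    Within each pacing period the deflection follows
    (1 - exp(-t/tau_rise)) * exp(-t/tau_decay), normalized so its peak
    equals ``peak_deflection_um``.
    """
    period = 1.0 / truth.twitch_frequency_hz
    tt = np.mod(t, period)
    a, b = truth.rise_tau_s, truth.decay_tau_s
    w = (1.0 - np.exp(-tt / a)) * np.exp(-tt / b)
    t_pk = a * np.log(1 + b / a)  # argmax of the product form
    peak = (1.0 - np.exp(-t_pk / a)) * np.exp(-t_pk / b)
    return truth.peak_deflection_um * w / peak


def _disc(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(yy - cy, xx - cx)
    # soft edge ~1.5 px wide for sub-pixel centroid fidelity
    return 1.0 / (1.0 + np.exp((d - radius) / 0.75))


def simulate_twitch_video(
    truth: TwitchTruth,
    n_frames: int = 330,
    fps: float = 66.0,
    um_per_px: float = 8.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (64, 160),
    post_radius_px: float = 9.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-post twitch video; returns (stack, truth trace in um).

    The rigid post is fixed; the flexible post's centroid moves toward
    the rigid post by the twitch waveform. Frames carry optional
    Gaussian pixel noise (``noise_sd`` as a fraction of full scale).
    """
    if n_frames < fps / truth.twitch_frequency_hz:
        raise ValueError("n_frames must cover at least one full twitch")
    rng = stage_rng(seed, "twitch")
    h, w = frame_shape
    sep_px = truth.baseline_separation_um / um_per_px
    rigid_x = (w - sep_px) / 2
    flex_x0 = rigid_x + sep_px
    if not (post_radius_px < rigid_x and flex_x0 + post_radius_px < w - 1):
        raise ValueError("posts/deflection exceed frame bounds")
    cy = h / 2

    t = np.arange(n_frames) / fps
    trace = twitch_waveform(t, truth)
    stack = np.empty((n_frames, h, w), dtype=np.float32)
    rigid_img = _disc(frame_shape, cy, rigid_x, post_radius_px)
    for i in range(n_frames):
        flex_x = flex_x0 - trace[i] / um_per_px
        frame = rigid_img + _disc(frame_shape, cy, flex_x, post_radius_px)
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, size=frame.shape)
        stack[i] = np.clip(frame, 0, None)
    return stack, trace


# ---------------------------------------------------------------------------
# MEA beat tables


def simulate_field_potentials(
    beat_period_s: float,
    fpd_s: float,
    n_electrodes: int = 4,
    n_beats: int = 40,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-electrode beat table with Gaussian jitter on period and FPD."""
    if not fpd_s < beat_period_s:
        raise ValueError("fpd must be smaller than the beat period")
    rng = stage_rng(seed, "mea")
    rows = []
    for e in range(n_electrodes):
        for b in range(n_beats):
            period = beat_period_s + (rng.normal(0, jitter_sd) if jitter_sd else 0.0)
            fpd = fpd_s + (rng.normal(0, jitter_sd) if jitter_sd else 0.0)
            fpd = min(max(fpd, 1e-3), period - 1e-3)
            rows.append(
                {"electrode": f"e{e + 1}", "beat": b + 1, "period_s": period, "fpd_s": fpd}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3D volumes


def simulate_volume_masks(
    shape: tuple[int, int, int] = (24, 96, 96),
    nuclear_fraction_of_signal: float = 0.6,
    n_puncta: int = 400,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Punctate 3D signal with an exact nuclear intensity fraction.

    An ellipsoidal nuclear mask sits at the volume center; puncta are
    single-voxel intensities placed inside and outside the mask, with
    the inside intensities rescaled so the nuclear share of total
    signal equals the requested fraction exactly. Returns
    (intensity volume, nuclear mask).
    """
    if not 0 <= nuclear_fraction_of_signal <= 1:
        raise ValueError("nuclear_fraction_of_signal must be in [0, 1]")
    rng = stage_rng(seed, "volume")
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    c = [(s - 1) / 2 for s in shape]
    axes = [s / 4 for s in shape]
    mask = (
        ((zz - c[0]) / axes[0]) ** 2
        + ((yy - c[1]) / axes[1]) ** 2
        + ((xx - c[2]) / axes[2]) ** 2
    ) <= 1.0

    vol = np.zeros(shape, dtype=np.float64)
    inside = np.flatnonzero(mask.ravel())
    outside = np.flatnonzero(~mask.ravel())
    n_in = n_puncta // 2
    n_out = n_puncta - n_in
    idx_in = rng.choice(inside, size=n_in, replace=False)
    idx_out = rng.choice(outside, size=n_out, replace=False)
    flat = vol.ravel()
    flat[idx_in] = rng.uniform(0.5, 1.0, size=n_in)
    flat[idx_out] = rng.uniform(0.5, 1.0, size=n_out)

    f = nuclear_fraction_of_signal
    s_in = flat[idx_in].sum()
    s_out = flat[idx_out].sum()
    if f == 0:
        flat[idx_in] = 0.0
    elif f == 1:
        flat[idx_out] = 0.0
    else:
        flat[idx_in] *= (f * s_out) / ((1 - f) * s_in)
    return vol, mask
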