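"""Self-contained miniature study generator.

Produces a random genome, planted G4-motif candidate intervals, a chromatin
accessibility track, and in vivo peaks over the *active* subset — the same
object shapes as a real cell line (G4-seq candidates, ATAC-seq signal, G4
ChIP-seq/CUT&Tag peaks), with the ground truth kept in a separate table that
no pipeline step reads.

By default activity is encoded only through accessibility: every candidate
carries the same motif family, and active candidates get a Gaussian
accessibility bump, mirroring real data where sequence alone is a weak
predictor of in vivo folding while openness is strong. An optional
``seq_bias`` mode additionally plants a discriminative base at fixed offsets
so sequence-only models have something to find.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import ArrayTrack, DictGenome, GenomicInterval, PeakSet, write_bed

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_genome",
    "plant_candidates",
    "generate_atac_track",
    "generate_invivo_peaks",
    "generate_synthetic_study",
    "write_study",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifSpec:
    """A G4-like planted pattern: ``n_runs`` G-tracts of ``run_length`` Gs
    separated by random loops of ``loop_min..loop_max`` random bases."""

    n_runs: int = 4
    run_length: int = 3
    loop_min: int = 2
    loop_max: int = 7

    def __post_init__(self) -> None:
        if self.n_runs < 2 or self.run_length < 2:
            raise ValueError("motif needs >= 2 runs of >= 2 guanines")
        if not 1 <= self.loop_min <= self.loop_max:
            raise ValueError("need 1 <= loop_min <= loop_max")

    @property
    def max_length(self) -> int:
        return self.n_runs * self.run_length + (self.n_runs - 1) * self.loop_max

    def sample(self, rng: np.random.Generator) -> str:
        parts = ["G" * self.run_length]
        for _ in range(self.n_runs - 1):
            loop_len = int(rng.integers(self.loop_min, self.loop_max + 1))
            parts.append("".join(rng.choice(_BASES, size=loop_len)))
            parts.append("G" * self.run_length)
        return "".join(parts)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study geometry and planted effect sizes.

    The defaults emulate the real problem's shape at desk scale: a skewed
    active fraction (~1%, as in real cell lines where ~4k of ~434k candidates
    are active), accessibility bumps of a few signal units over sub-unit
    noise, and in vivo peaks (half-width 75 bp, near the 100-500 bp
    resolution of the underlying assays) centered on active candidates. The
    peak half-width is paired with the motif geometry so the default 10%
    peak-length overlap threshold (15 bp) never exceeds the shortest planted
    motif (18 bp): labeling then recovers the planted truth exactly.
    ``min_spacing`` keeps candidate centers far enough apart that one
    candidate's peak or bump cannot contaminate a neighbour's label or
    feature window.
    """

    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_candidates: int = 2000
    active_fraction: float = 0.01
    atac_peak_height: float = 4.0
    atac_peak_sd: float = 150.0
    background_noise_sd: float = 0.25
    background_block: int = 20
    invivo_peak_halfwidth: int = 75
    invivo_peak_jitter: int = 0
    min_spacing: int = 2000
    edge_margin: int = 1100
    motif: MotifSpec = field(default_factory=MotifSpec)
    seq_bias: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must be in (0, 1)")
        for name in (
            "n_chroms", "chrom_length", "n_candidates", "invivo_peak_halfwidth",
            "min_spacing", "background_block",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticStudy:
    """In-memory study bundle; ``truth`` is ground truth, for tests only."""

    genome: DictGenome
    candidates: PeakSet
    track: ArrayTrack
    invivo: PeakSet
    truth: pd.DataFrame
    config: SyntheticConfig
    seed: int


def _child(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def generate_genome(cfg: SyntheticConfig, seed: int) -> DictGenome:
    """I.i.d. uniform-ACGT chromosomes named chr1..chrN; no Ns."""
    rng = _child(seed, 0)
    seqs = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=cfg.chrom_length))
        for i in range(cfg.n_chroms)
    }
    return DictGenome(seqs)


def plant_candidates(
    genome: DictGenome, cfg: SyntheticConfig, seed: int
) -> tuple[DictGenome, PeakSet, pd.DataFrame]:
    """Overwrite non-overlapping loci with motif instances; Bernoulli-mark actives.

    Returns the modified genome, the candidate set (BED-shaped, named, random
    strand), and the hidden truth table. Candidate centers keep
    ``min_spacing`` from each other and ``edge_margin`` from chromosome ends
    so feature windows fit without padding and labels cannot bleed between
    neighbours.
    """
    rng = _child(seed, 1)
    usable = cfg.chrom_length - 2 * cfg.edge_margin
    slots_per_chrom = usable // cfg.min_spacing
    total_slots = slots_per_chrom * cfg.n_chroms
    if total_slots < cfg.n_candidates:
        raise ValueError(
            f"genome too small: {total_slots} candidate slots < "
            f"{cfg.n_candidates} requested"
        )
    chosen = rng.choice(total_slots, size=cfg.n_candidates, replace=False)
    chosen.sort()

    seqs = {c: list(genome._raw_fetch(c, 0, genome.sizes[c])) for c in genome.sizes}
    chrom_names = sorted(genome.sizes)
    records = []
    intervals = []
    active = rng.random(cfg.n_candidates) < cfg.active_fraction
    for i, slot in enumerate(chosen):
        chrom = chrom_names[slot // slots_per_chrom]
        center = cfg.edge_margin + (slot % slots_per_chrom) * cfg.min_spacing
        motif = cfg.motif.sample(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if cfg.seq_bias and active[i]:
            # discriminative base at a fixed offset inside the first loop
            motif = motif[: cfg.motif.run_length] + "A" + motif[cfg.motif.run_length + 1 :]
        planted = motif if strand == "+" else _revcomp(motif)
        start = center - len(planted) // 2
        seqs[chrom][start : start + len(planted)] = list(planted)
        iv = GenomicInterval(
            chrom, start, start + len(planted), strand, name=f"g4_{i:05d}"
        )
        intervals.append(iv)
        records.append(
            {
                "id": iv.name,
                "chrom": chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": strand,
                "center": iv.center,
                "active": int(active[i]),
            }
        )
    new_genome = DictGenome({c: "".join(s) for c, s in seqs.items()})
    return new_genome, PeakSet(intervals), pd.DataFrame(records)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def generate_atac_track(
    truth: pd.DataFrame, cfg: SyntheticConfig, seed: int,
    sizes: dict[str, int] | None = None,
) -> ArrayTrack:
    """Blocky half-normal background plus a Gaussian bump on each active center."""
    rng = _child(seed, 2)
    sizes = sizes or {
        f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)
    }
    arrays = {}
    for chrom, size in sizes.items():
        n_blocks = -(-size // cfg.background_block)
        blocks = np.abs(rng.normal(0.0, cfg.background_noise_sd, size=n_blocks))
        arrays[chrom] = np.repeat(blocks, cfg.background_block)[:size].copy()
    if cfg.atac_peak_height > 0:
        half = int(4 * cfg.atac_peak_sd)
        offsets = np.arange(-half, half + 1)
        bump = cfg.atac_peak_height * np.exp(
            -(offsets**2) / (2 * cfg.atac_peak_sd**2)
        )
        for row in truth.itertuples():
            if not row.active:
                continue
            arr = arrays[row.chrom]
            lo, hi = row.center - half, row.center + half + 1
            blo, bhi = max(lo, 0), min(hi, len(arr))
            arr[blo:bhi] += bump[blo - lo : bhi - lo]
    return ArrayTrack(arrays)


def generate_invivo_peaks(
    truth: pd.DataFrame, cfg: SyntheticConfig, seed: int
) -> PeakSet:
    """One peak of half-width ``invivo_peak_halfwidth`` per active candidate."""
    rng = _child(seed, 3)
    peaks = []
    for k, row in enumerate(truth.itertuples()):
        if not row.active:
            continue
        jitter = (
            int(rng.integers(-cfg.invivo_peak_jitter, cfg.invivo_peak_jitter + 1))
            if cfg.invivo_peak_jitter
            else 0
        )
        c = row.center + jitter
        peaks.append(
            GenomicInterval(
                row.chrom,
                c - cfg.invivo_peak_halfwidth,
                c + cfg.invivo_peak_halfwidth,
                name=f"peak_{k:05d}",
            )
        )
    return PeakSet(peaks)


def generate_synthetic_study(cfg: SyntheticConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Orchestrate genome -> candidates -> accessibility -> peaks in memory."""
    cfg = cfg or SyntheticConfig()
    genome = generate_genome(cfg, seed)
    genome, candidates, truth = plant_candidates(genome, cfg, seed)
    track = generate_atac_track(truth, cfg, seed, sizes=dict(genome.sizes))
    invivo = generate_invivo_peaks(truth, cfg, seed)
    return SyntheticStudy(genome, candidates, track, invivo, truth, cfg, seed)


def write_study(study: SyntheticStudy, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the study as standard files: FASTA, BEDs, bedGraph, truth TSV,
    and a manifest recording config + seed. Returns the path map.

    The truth TSV exists only for validation; no pipeline command reads it.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "candidates": str(out / "candidates.bed"),
        "atac": str(out / "atac.bedgraph"),
        "invivo": str(out / "invivo_peaks.bed"),
        "truth": str(out / "truth.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(study.genome.sizes):
            fh.write(f">{chrom}\n")
            seq = study.genome._raw_fetch(chrom, 0, study.genome.sizes[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_bed(study.candidates, paths["candidates"])
    write_bed(study.invivo, paths["invivo"])
    _write_bedgraph(study.track, paths["atac"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(study.config)
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": cfg, "seed": study.seed}, fh, indent=2, sort_keys=True)
    return paths


def _write_bedgraph(track: ArrayTrack, path: str) -> None:
    """Run-length-merged 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.sizes):
            arr = track._arrays[chrom]
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.r_[0, change]
            ends = np.r_[change, len(arr)]
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
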