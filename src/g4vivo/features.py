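"""Feature construction: windowed accessibility means plus ordinal-encoded sequence.

Each candidate is extended to a fixed-width region around its center (1 kb
each side by default). The region yields two feature blocks:

* accessibility — the per-base signal averaged in non-overlapping windows
  (10 bp by default), giving 200 floats;
* sequence — every base ordinally encoded A->0, T->1, C->2, G->3 (anything
  else -> 4), giving 2000 integer codes that downstream tree learners treat
  as unordered categorical variables.

``signal_profile`` reuses the same center-anchored binning to aggregate any
signal (e.g. histone-modification tracks) around a set of sites.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    fetch_sequence,
    fetch_signal,
)
from .labeling import LabeledCandidates

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "extend_to_region",
    "atac_feature",
    "sequence_feature",
    "build_feature_matrix",
    "signal_profile",
    "FEATURE_MODES",
]

FEATURE_MODES = ("both", "atac", "seq")

_DEFAULT_CODES = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class FeatureConfig:
    """Geometry and encoding of the feature region.

    flank
        bp each side of the candidate center (default 1000 -> 2 kb region).
    window
        accessibility bin width in bp (default 10 -> 200 bins).
    base_codes / unknown_code
        ordinal encoding of the four bases; N and ambiguity codes collapse
        to ``unknown_code`` so the region keeps its fixed length.
    strand_orient
        when True (default), minus-strand candidates are reverse-complemented
        and their accessibility vector reversed, so features read 5'->3' on
        the candidate strand.
    """

    flank: int = 1000
    window: int = 10
    base_codes: dict = field(default_factory=lambda: dict(_DEFAULT_CODES))
    unknown_code: int = 4
    strand_orient: bool = True

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.window <= 0:
            raise ValueError("flank and window must be positive")
        if (2 * self.flank) % self.window != 0:
            raise ValueError("window must divide the region length 2*flank")

    @property
    def region_length(self) -> int:
        return 2 * self.flank

    @property
    def n_windows(self) -> int:
        return self.region_length // self.window

    def _encode_table(self) -> np.ndarray:
        table = np.full(256, self.unknown_code, dtype=np.int16)
        for base, code in self.base_codes.items():
            table[ord(base)] = code
            table[ord(base.lower())] = code
        return table


def extend_to_region(iv: GenomicInterval, cfg: FeatureConfig) -> GenomicInterval:
    """Center-anchored fixed-width region: ``[center - flank, center + flank)``.

    The center of an odd-length interval is its floor midpoint. Strand is
    preserved; a start that falls below zero is legal here and padded at
    fetch time.
    """
    c = iv.center
    return GenomicInterval(iv.chrom, c - cfg.flank, c + cfg.flank, iv.strand, iv.name)


def atac_feature(
    region: GenomicInterval, track: SignalTrack, cfg: FeatureConfig
) -> np.ndarray:
    """Mean signal in each non-overlapping window of the region.

    Minus-strand regions are reversed when ``cfg.strand_orient`` so window 0
    is always the candidate-strand 5' end.
    """
    if region.length != cfg.region_length:
        raise ValueError(
            f"region length {region.length} != 2*flank = {cfg.region_length}"
        )
    vals = fetch_signal(track, region)
    means = vals.reshape(cfg.n_windows, cfg.window).mean(axis=1)
    if cfg.strand_orient and region.strand == "-":
        means = means[::-1]
    return means


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sequence_feature(
    region: GenomicInterval, genome: GenomeSequence, cfg: FeatureConfig
) -> np.ndarray:
    """Ordinal base codes for the region, oriented 5'->3' on the candidate strand."""
    if region.length != cfg.region_length:
        raise ValueError(
            f"region length {region.length} != 2*flank = {cfg.region_length}"
        )
    seq = fetch_sequence(genome, region)
    if cfg.strand_orient and region.strand == "-":
        seq = reverse_complement(seq)
    table = cfg._encode_table()
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class FeatureMatrix:
    """Row-per-candidate feature matrix with a categorical-column schema.

    ``data`` is a dense float64 matrix; in ``both`` mode the first
    ``n_windows`` columns are accessibility means and the remaining
    ``2 * flank`` columns carry integer category codes, flagged by
    ``categorical_mask`` for the tree learner.
    """

    def __init__(
        self,
        data: np.ndarray,
        categorical_mask: np.ndarray,
        mode: str,
        config: FeatureConfig,
    ):
        data = np.asarray(data, dtype=np.float64)
        categorical_mask = np.asarray(categorical_mask, dtype=bool)
        if data.ndim != 2 or data.shape[1] != categorical_mask.size:
            raise ValueError("data / categorical_mask shape mismatch")
        if mode not in FEATURE_MODES:
            raise ValueError(f"mode must be one of {FEATURE_MODES}")
        self.data = data
        self.categorical_mask = categorical_mask
        self.mode = mode
        self.config = config

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def categorical_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.categorical_mask)]

    def column_names(self) -> list[str]:
        cfg = self.config
        names = []
        if self.mode in ("both", "atac"):
            names += [f"atac_{i}" for i in range(cfg.n_windows)]
        if self.mode in ("both", "seq"):
            names += [f"seq_{i}" for i in range(cfg.region_length)]
        return names

    def schema_digest(self) -> str:
        payload = json.dumps(
            {
                "n_columns": self.n_columns,
                "categorical": self.categorical_indices,
                "mode": self.mode,
                "flank": self.config.flank,
                "window": self.config.window,
                "strand_orient": self.config.strand_orient,
                "unknown_code": self.config.unknown_code,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def subset(self, mode: str) -> "FeatureMatrix":
        """Restrict to a feature block: ``atac``, ``seq`` or ``both``."""
        if mode == self.mode:
            return self
        if self.mode != "both":
            raise ValueError(f"cannot take {mode!r} subset of a {self.mode!r} matrix")
        n_atac = self.config.n_windows
        if mode == "atac":
            return FeatureMatrix(
                self.data[:, :n_atac], np.zeros(n_atac, bool), "atac", self.config
            )
        if mode == "seq":
            n_seq = self.config.region_length
            return FeatureMatrix(
                self.data[:, n_atac:], np.ones(n_seq, bool), "seq", self.config
            )
        raise ValueError(f"mode must be one of {FEATURE_MODES}")

    def take(self, indices: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.data[indices], self.categorical_mask, self.mode, self.config
        )


def build_feature_matrix(
    cands: LabeledCandidates | PeakSet,
    track: SignalTrack | None,
    genome: GenomeSequence | None,
    cfg: FeatureConfig | None = None,
    mode: str = "both",
) -> FeatureMatrix:
    """Featurize every candidate, preserving row order.

    ``mode`` selects the feature blocks (``both`` / ``atac`` / ``seq``) for
    ablation experiments; only the required input (track and/or genome) needs
    to be supplied. Raises on chromosome-name mismatches, listing offenders.
    """
    cfg = cfg or FeatureConfig()
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    intervals = cands.candidates if isinstance(cands, LabeledCandidates) else list(cands)

    need_track = mode in ("both", "atac")
    need_genome = mode in ("both", "seq")
    if need_track and track is None:
        raise ValueError("signal track required for mode " + mode)
    if need_genome and genome is None:
        raise ValueError("genome required for mode " + mode)
    chrom_sources = []
    if need_genome:
        chrom_sources.append(genome)
    if need_track:
        chrom_sources.append(track)
    chroms = {iv.chrom for iv in intervals}
    for src in chrom_sources:
        missing = sorted(chroms - set(src.sizes))
        if missing:
            raise ValueError(
                f"chromosome-name mismatch: {missing} absent from "
                f"{'genome' if isinstance(src, GenomeSequence) else 'signal track'}"
            )

    n_atac = cfg.n_windows if need_track else 0
    n_seq = cfg.region_length if need_genome else 0
    data = np.empty((len(intervals), n_atac + n_seq), dtype=np.float64)
    for i, iv in enumerate(intervals):
        region = extend_to_region(iv, cfg)
        if need_track:
            data[i, :n_atac] = atac_feature(region, track, cfg)
        if need_genome:
            data[i, n_atac:] = sequence_feature(region, genome, cfg)
    mask = np.r_[np.zeros(n_atac, bool), np.ones(n_seq, bool)]
    return FeatureMatrix(data, mask, mode, cfg)


def signal_profile(
    sites: PeakSet,
    track: SignalTrack,
    flank: int = 1000,
    binsize: int = 10,
    aggregate: str = "mean",
) -> np.ndarray:
    """Binned signal around site centers, averaged across sites or per site.

    ``aggregate="mean"`` returns the across-site column mean (line-chart
    substrate); ``"per_site_matrix"`` returns one row per site (heatmap
    substrate; its row means are the boxplot substrate). Sites are binned
    exactly like the accessibility feature, including strand orientation.
    """
    if len(sites) == 0:
        raise ValueError("signal_profile requires at least one site")
    if (2 * flank) % binsize != 0:
        raise ValueError("binsize must divide 2*flank")
    if aggregate not in ("mean", "per_site_matrix"):
        raise ValueError("aggregate must be 'mean' or 'per_site_matrix'")
    cfg = FeatureConfig(flank=flank, window=binsize)
    mat = np.empty((len(sites), cfg.n_windows), dtype=np.float64)
    for i, site in enumerate(sites):
        mat[i] = atac_feature(extend_to_region(site, cfg), track, cfg)
    return mat.mean(axis=0) if aggregate == "mean" else mat
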