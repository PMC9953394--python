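"""Active/inactive labeling of candidate G4 intervals by fractional overlap.

A candidate detected in vitro (e.g. a G4-seq entry) is called *active* in a
cell type when it overlaps an in vivo G4 peak (G4 ChIP-seq or CUT&Tag) by at
least a configurable fraction of a reference length. The default threshold is
10% of the in vivo peak's length; measuring the fraction against the
candidate's own length instead is available via ``fraction_of="candidate"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomicInterval, PeakSet

__all__ = ["LabelConfig", "LabeledCandidates", "overlap_length", "label_entries"]


@dataclass(frozen=True)
class LabelConfig:
    """How a candidate/peak overlap is judged sufficient.

    overlap_fraction
        Fraction in (0, 1] of the reference length that must be covered;
        default 0.10.
    fraction_of
        ``"peak"`` (reference = the in vivo peak, default) or ``"candidate"``.
    aggregation
        ``"per_peak"`` (one sufficient peak makes a positive, default) or
        ``"summed"`` (total overlap across peaks, candidate-relative only).
    """

    overlap_fraction: float = 0.10
    fraction_of: str = "peak"
    aggregation: str = "per_peak"

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.fraction_of not in ("peak", "candidate"):
            raise ValueError("fraction_of must be 'peak' or 'candidate'")
        if self.aggregation not in ("per_peak", "summed"):
            raise ValueError("aggregation must be 'per_peak' or 'summed'")
        if self.aggregation == "summed" and self.fraction_of == "peak":
            raise ValueError(
                "summed aggregation requires fraction_of='candidate': a summed "
                "overlap has no single peak length to take a fraction of"
            )


@dataclass
class LabeledCandidates:
    """Candidates plus a parallel 0/1 activity vector (1 = active/positive)."""

    candidates: list[GenomicInterval]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.candidates) != len(self.labels):
            raise ValueError("candidates and labels differ in length")

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 across chromosomes. Strand ignored."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def label_entries(
    candidates: PeakSet, invivo: PeakSet, cfg: LabelConfig | None = None
) -> LabeledCandidates:
    """Partition candidates into active (1) and inactive (0) samples.

    Per-peak mode: a candidate is positive iff some in vivo peak ``p``
    overlaps it by ``>= overlap_fraction * len(reference)`` where the
    reference is ``p`` or the candidate per ``cfg.fraction_of``. Summed mode
    compares total overlap across all peaks against the candidate-relative
    threshold. Labels do not depend on the input ordering (both sets are
    sorted collections).
    """
    cfg = cfg or LabelConfig()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in invivo:
        by_chrom.setdefault(p.chrom, []).append(p)
    # peaks are sorted by start within a chromosome; a running max of ends is
    # non-decreasing, so both scan bounds come from binary searches
    starts = {c: np.array([p.start for p in ps]) for c, ps in by_chrom.items()}
    cummax_end = {
        c: np.maximum.accumulate([p.end for p in ps]) for c, ps in by_chrom.items()
    }

    labels = np.zeros(len(candidates), dtype=np.int8)
    for i, cand in enumerate(candidates):
        ps = by_chrom.get(cand.chrom)
        if not ps:
            continue
        # overlap requires p.start < cand.end and p.end > cand.start
        lo = int(np.searchsorted(cummax_end[cand.chrom], cand.start, side="right"))
        hi = int(np.searchsorted(starts[cand.chrom], cand.end, side="left"))
        total = 0
        for p in ps[lo:hi]:
            ov = overlap_length(cand, p)
            if ov == 0:
                continue
            if cfg.aggregation == "summed":
                total += ov
            else:
                ref_len = p.length if cfg.fraction_of == "peak" else cand.length
                if ov >= cfg.overlap_fraction * ref_len:
                    labels[i] = 1
                    break
        if cfg.aggregation == "summed" and total >= cfg.overlap_fraction * cand.length:
            labels[i] = 1
    return LabeledCandidates(list(candidates), labels)
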