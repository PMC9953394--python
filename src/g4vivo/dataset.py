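"""Labeled datasets, stratified half-splitting, and minority oversampling.

The evaluation protocol for the skewed active/inactive G4 problem is: split
each cell line's labeled pool 50/50 at random while preserving the class
ratio in both halves, duplicate positive training rows at random until the
training classes are equal, and leave the test half untouched.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureMatrix
from .genome_io import GenomicInterval
from .labeling import LabeledCandidates

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "stratified_half_split",
    "oversample_positives",
    "save_dataset",
    "load_dataset",
]


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels + unique row identifiers.

    ``intervals`` (optional) keeps the genomic coordinates aligned to rows so
    predictions can be written back as BED.
    """

    features: FeatureMatrix
    labels: np.ndarray
    ids: np.ndarray
    intervals: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.ids = np.asarray(self.ids, dtype=object)
        n = self.features.n_rows
        if not (len(self.labels) == len(self.ids) == n):
            raise ValueError("features, labels and ids must have equal length")
        if len(set(self.ids)) != n:
            raise ValueError("ids must be unique")
        if self.intervals is not None and len(self.intervals) != n:
            raise ValueError("intervals must align with rows")

    def __len__(self) -> int:
        return self.features.n_rows

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def take(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices)
        ivs = [self.intervals[i] for i in indices] if self.intervals else None
        return LabeledDataset(
            self.features.take(indices), self.labels[indices], self.ids[indices], ivs
        )

    def with_mode(self, mode: str) -> "LabeledDataset":
        """Same rows, restricted feature block (ablation helper)."""
        return LabeledDataset(
            self.features.subset(mode), self.labels, self.ids, self.intervals
        )

    @classmethod
    def from_labeled_candidates(
        cls, cands: LabeledCandidates, features: FeatureMatrix
    ) -> "LabeledDataset":
        ids = np.array(
            [iv.name or f"cand_{i}" for i, iv in enumerate(cands.candidates)],
            dtype=object,
        )
        if len(set(ids)) != len(ids):  # fall back to positional ids
            ids = np.array([f"cand_{i}" for i in range(len(cands))], dtype=object)
        return cls(features, cands.labels, ids, list(cands.candidates))


@dataclass(frozen=True)
class SplitSpec:
    """Per-class random split: train takes ``floor(train_fraction * n_class)``."""

    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_half_split(
    ds: LabeledDataset, spec: SplitSpec | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random class-stratified partition into train and test.

    Within each class the training half receives exactly
    ``floor(train_fraction * n_class)`` members drawn uniformly without
    replacement under ``spec.seed``; the test half receives the remainder, so
    with an odd class count the extra member lands in the test set.
    """
    spec = spec or SplitSpec()
    if ds.n_positive == 0 or ds.n_negative == 0:
        raise ValueError("both classes must be non-empty for a stratified split")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.flatnonzero(ds.labels == cls)
        perm = rng.permutation(members)
        n_train = int(np.floor(spec.train_fraction * len(members)))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return ds.take(train), ds.take(test)


def oversample_positives(ds: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Duplicate positive rows uniformly at random until classes are equal.

    Pure duplication — no synthetic feature values are created. Every
    original row is present at least once; copies get ``|dupN`` id suffixes
    to keep ids unique. Requires ``1 <= n_pos <= n_neg``.
    """
    n_pos, n_neg = ds.n_positive, ds.n_negative
    if n_pos < 1:
        raise ValueError("oversampling requires at least one positive sample")
    if n_pos > n_neg:
        raise ValueError(
            f"positives ({n_pos}) outnumber negatives ({n_neg}); "
            "oversampling direction undefined"
        )
    if n_pos == n_neg:
        return ds
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(ds.labels == 1)
    extra = rng.choice(pos, size=n_neg - n_pos, replace=True)
    all_idx = np.concatenate([np.arange(len(ds)), extra])
    ids = np.concatenate(
        [ds.ids, [f"{ds.ids[j]}|dup{k}" for k, j in enumerate(extra)]]
    ).astype(object)
    ivs = [ds.intervals[i] for i in all_idx] if ds.intervals else None
    return LabeledDataset(
        ds.features.take(all_idx), ds.labels[all_idx], ids, ivs
    )


# ---------------------------------------------------------------------------
# TSV persistence (plain text; .gz honored by pandas via the extension)

_META_COLS = ["id", "chrom", "start", "end", "strand", "label"]


def save_dataset(ds: LabeledDataset, path: str | os.PathLike) -> None:
    """Write rows as TSV with a JSON sidecar (``<path>.schema.json``)."""
    fm = ds.features
    cols = fm.column_names()
    df = pd.DataFrame(fm.data, columns=cols)
    if ds.intervals is not None:
        meta = pd.DataFrame(
            {
                "id": ds.ids,
                "chrom": [iv.chrom for iv in ds.intervals],
                "start": [iv.start for iv in ds.intervals],
                "end": [iv.end for iv in ds.intervals],
                "strand": [iv.strand for iv in ds.intervals],
                "label": ds.labels,
            }
        )
    else:
        meta = pd.DataFrame({"id": ds.ids, "label": ds.labels})
    pd.concat([meta.reset_index(drop=True), df], axis=1).to_csv(
        path, sep="\t", index=False
    )
    schema = {
        "mode": fm.mode,
        "flank": fm.config.flank,
        "window": fm.config.window,
        "strand_orient": fm.config.strand_orient,
        "unknown_code": fm.config.unknown_code,
        "categorical_columns": [cols[i] for i in fm.categorical_indices],
        "n_rows": fm.n_rows,
        "schema_digest": fm.schema_digest(),
    }
    with open(f"{path}.schema.json", "w") as fh:
        json.dump(schema, fh, indent=2)


def load_dataset(path: str | os.PathLike) -> LabeledDataset:
    """Read a dataset written by :func:`save_dataset`."""
    with open(f"{path}.schema.json") as fh:
        schema = json.load(fh)
    df = pd.read_csv(path, sep="\t")
    cfg = FeatureConfig(
        flank=schema["flank"],
        window=schema["window"],
        strand_orient=schema["strand_orient"],
        unknown_code=schema["unknown_code"],
    )
    feat_cols = [c for c in df.columns if c.startswith(("atac_", "seq_"))]
    mask = np.array([c.startswith("seq_") for c in feat_cols], dtype=bool)
    fm = FeatureMatrix(df[feat_cols].to_numpy(float), mask, schema["mode"], cfg)
    intervals = None
    if "chrom" in df.columns:
        intervals = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, str(r.id))
            for r in df.itertuples()
        ]
    return LabeledDataset(
        fm, df["label"].to_numpy(np.int8), df["id"].astype(str).to_numpy(object),
        intervals,
    )
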