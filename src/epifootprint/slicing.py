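"""Mark-ROI "data slices": regions x samples matrices of mean signal.

A data slice is the unit of all downstream analysis: for one histone mark and
one region-of-interest class, each column holds one sample's base-pair-weighted
mean signal over every region.  Slices are quantile-normalized between
epigenomes before clustering or differential testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import RegionSet, SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class DataSlice:
    """Regions x samples matrix of mean signal for one mark-ROI pair."""

    mark: str
    roi_class: str
    region_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    _allow_duplicate_rows: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_names), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.region_names)} regions x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("slice values must be finite")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if not self._allow_duplicate_rows and len(set(self.region_names)) != len(
            self.region_names
        ):
            raise ValueError("duplicate region names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_names, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "region"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, mark: str, roi_class: str) -> "DataSlice":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(mark, roi_class, list(df.index), list(df.columns), df.to_numpy())


def aggregate_signal(track: SignalTrack, regions: RegionSet) -> np.ndarray:
    """Base-pair-weighted mean track signal per region (gaps count as 0).

    Regions on chromosomes absent from the track get mean 0 (logged once).
    """
    by_chrom = {}
    for chrom, sub in track.data.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(dtype=float),
        )
    out = np.zeros(len(regions), dtype=float)
    missing_chroms = set()
    for idx, region in enumerate(regions):
        arrs = by_chrom.get(region.chrom)
        if arrs is None:
            missing_chroms.add(region.chrom)
            continue
        starts, ends, values = arrs
        # track intervals are sorted and disjoint: overlap candidates span
        # the first interval ending after region.start to the last starting
        # before region.end
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        out[idx] = float(np.dot(np.clip(ov, 0, None), values[lo:hi])) / len(region)
    if missing_chroms:
        logger.info(
            "track %s/%s: no signal on chromosome(s) %s; affected regions set to 0",
            track.sample_id,
            track.replicate_id,
            sorted(missing_chroms),
        )
    return out


def build_data_slice(
    tracks: list[SignalTrack], regions: RegionSet, mark: str
) -> DataSlice:
    """Assemble a slice from exactly one track per sample, all of one mark."""
    sample_ids = [t.sample_id for t in tracks]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among tracks")
    for t in tracks:
        if t.mark != mark:
            raise ValueError(f"track {t.sample_id} has mark {t.mark}, expected {mark}")
    values = np.column_stack([aggregate_signal(t, regions) for t in tracks])
    return DataSlice(mark, regions.roi_class, list(regions.names), sample_ids, values)


def quantile_normalize(slice_: DataSlice) -> DataSlice:
    """Quantile normalization across sample columns.

    Each column's values are replaced by the across-column means of the order
    statistics at their ranks; within a column, tied values receive the mean
    of the reference values over their tied positions, so column value
    multisets become identical.
    """
    X = slice_.values
    n_rows, n_cols = X.shape
    if n_cols < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return slice_
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    rows = np.arange(n_rows)
    for j in range(n_cols):
        assigned = np.empty(n_rows, dtype=float)
        assigned[order[:, j]] = reference
        # average reference values over ties in the input column
        uniq, inverse, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        if len(uniq) < n_rows:
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return DataSlice(
        slice_.mark,
        slice_.roi_class,
        list(slice_.region_names),
        list(slice_.sample_ids),
        out,
    )


def log2_slice(slice_: DataSlice, pseudocount: float = 1.0) -> DataSlice:
    """log2(x + pseudocount) transform, for roughly Gaussian modelling."""
    return DataSlice(
        slice_.mark,
        slice_.roi_class,
        list(slice_.region_names),
        list(slice_.sample_ids),
        np.log2(slice_.values + pseudocount),
    )
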