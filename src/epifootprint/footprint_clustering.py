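"""K-means clustering of binned multi-mark signal footprints at TSS windows.

A footprint is the concatenation, over (stage x mark), of per-bin mean signal
across a window centred on a TSS (defaults: 3 kb window, 100 bp bins, so 30
bins per mark; 5 marks x 1 stage = 150 features, 3 stages = 450).  Windows on
the minus strand are reversed so bins always read 5' to 3'.  Features are
scaled per (stage, mark) block by the block's 95th percentile and capped at 1
so no single mark dominates the Euclidean metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import GenomicInterval, RegionSet, SignalTrack, StateSegmentation
from .state_dynamics import assign_states


@dataclass
class FootprintMatrix:
    """Windows x features matrix with (stage, mark, bin) feature labels."""

    tss_names: list[str]
    feature_labels: list[tuple]  # (stage, mark, bin_index)
    values: np.ndarray
    window: int
    bin_size: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.tss_names), len(self.feature_labels))
        if self.values.shape != expected:
            raise ValueError(f"matrix shape {self.values.shape} != {expected}")

    def block(self, stage: str, mark: str) -> np.ndarray:
        cols = [i for i, (s, m, _) in enumerate(self.feature_labels) if s == stage and m == mark]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}|{m}|bin{b}" for s, m, b in self.feature_labels]
        return pd.DataFrame(self.values, index=self.tss_names, columns=cols)


def _binned_means(track: SignalTrack, window: GenomicInterval, bin_size: int) -> np.ndarray:
    """Base-weighted mean signal per bin of the window; gaps count as 0."""
    n_bins = len(window) // bin_size
    sub = track.data[track.data["chrom"] == window.chrom]
    out = np.zeros(n_bins, dtype=float)
    if len(sub):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        values = sub["value"].to_numpy(dtype=float)
        for b in range(n_bins):
            bs = window.start + b * bin_size
            be = bs + bin_size
            lo = np.searchsorted(ends, bs, side="right")
            hi = np.searchsorted(starts, be, side="left")
            if hi > lo:
                ov = np.minimum(ends[lo:hi], be) - np.maximum(starts[lo:hi], bs)
                out[b] = float(np.dot(np.clip(ov, 0, None), values[lo:hi])) / bin_size
    if window.strand == "-":
        out = out[::-1]
    return out


def build_footprints(
    tracks: dict[tuple, SignalTrack],
    tss: RegionSet,
    window: int = 3000,
    bin_size: int = 100,
) -> FootprintMatrix:
    """Bin signal of every (stage, mark) track over every TSS window.

    ``tracks`` maps (stage, mark) -> track; (stage, mark) pairs are laid out
    in their dict order, bins 5' to 3' within each pair.  TSS intervals are
    re-centred to ``window`` bp around their TSS.
    """
    if window % bin_size != 0:
        raise ValueError(f"window {window} not divisible by bin_size {bin_size}")
    from .io_formats import as_window

    windows = [as_window(iv, window) for iv in tss]
    feature_labels = []
    blocks = []
    n_bins = window // bin_size
    for (stage, mark), track in tracks.items():
        feature_labels.extend((stage, mark, b) for b in range(n_bins))
        block = np.vstack([_binned_means(track, w, bin_size) for w in windows])
        blocks.append(block)
    values = np.hstack(blocks)
    return FootprintMatrix([iv.name for iv in tss], feature_labels, values, window, bin_size)


def normalize_features(matrix: FootprintMatrix, percentile: float = 95.0) -> FootprintMatrix:
    """Per-(stage, mark) block scaling by the block's percentile, capped at 1.

    All-zero blocks are left at 0 (no NaNs); blocks whose percentile is 0 but
    that contain signal are scaled by their maximum instead.
    """
    out = matrix.values.copy()
    pairs = sorted({(s, m) for s, m, _ in matrix.feature_labels}, key=str)
    for stage, mark in pairs:
        cols = [
            i for i, (s, m, _) in enumerate(matrix.feature_labels) if (s, m) == (stage, mark)
        ]
        block = out[:, cols]
        scale = float(np.percentile(block, percentile))
        if scale <= 0:
            scale = float(block.max())
        if scale > 0:
            out[:, cols] = np.minimum(block / scale, 1.0)
    return FootprintMatrix(
        list(matrix.tss_names), list(matrix.feature_labels), out, matrix.window, matrix.bin_size
    )


@dataclass
class FootprintClusters:
    """K-means partition of TSS windows, labels 1..k ordered by size."""

    assignment: dict[str, int]
    centroids: np.ndarray
    k: int
    inertia: float

    def members(self, label: int) -> list[str]:
        return [t for t, c in self.assignment.items() if c == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tss": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def kmeans_cluster(
    matrix: FootprintMatrix, k: int, seed: int | None = None, n_init: int = 10
) -> FootprintClusters:
    """Euclidean k-means, best of ``n_init`` restarts; labels by decreasing size."""
    n = matrix.values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.values)
    sizes = np.bincount(raw, minlength=k)
    # stable relabel: largest cluster becomes 1
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    centroids = km.cluster_centers_[order]
    assignment = {t: int(c) for t, c in zip(matrix.tss_names, labels)}
    return FootprintClusters(assignment, centroids, k, float(km.inertia_))


def state_enrichment(
    clusters: FootprintClusters,
    segmentation: StateSegmentation,
    tss: RegionSet,
    window: int = 3000,
) -> pd.DataFrame:
    """Fold enrichment of each chromatin state within each footprint cluster.

    fold(c, s) = fraction of cluster-c windows in state s divided by the
    fraction of all windows in state s; states absent from the background are
    reported as fold 0 with ``undefined`` flagged.
    """
    from .io_formats import CHROMHMM_STATES, as_window

    windows = RegionSet(tss.roi_class, [as_window(iv, window) for iv in tss])
    states = assign_states(segmentation, windows)
    all_frac = pd.Series(list(states.values())).value_counts(normalize=True)
    rows = []
    for label in range(1, clusters.k + 1):
        members = clusters.members(label)
        member_states = pd.Series([states[m] for m in members])
        frac = member_states.value_counts(normalize=True)
        for s in CHROMHMM_STATES:
            bg = float(all_frac.get(s, 0.0))
            fg = float(frac.get(s, 0.0))
            rows.append(
                {
                    "cluster": label,
                    "state": s,
                    "cluster_fraction": fg,
                    "background_fraction": bg,
                    "fold": fg / bg if bg > 0 else 0.0,
                    "undefined": bg == 0,
                }
            )
    return pd.DataFrame(rows)
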