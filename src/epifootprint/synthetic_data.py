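"""Synthetic epigenomes with planted ground truth.

The generator emulates, at desk scale, the statistical structure the analysis
assumes in real reference-epigenome collections:

* clustered samples with replicate structure — groups of cell types whose
  histone-mark signal over a subset of regions is coherently elevated;
* cluster-specific marking — for designated "informative" mark-ROI
  combinations, a fraction of regions carries a log-scale signal elevation in
  exactly one sample cluster;
* multi-stage chromatin-state trajectories at TSS windows (bivalent →
  Polycomb-repressed → quiescent and friends) across an ordered series of
  differentiation stages;
* TF binding-site sets in which designated factors concentrate their sites
  inside a region set.

Signal is log-normal: per-region log2 baselines are Normal(mu0, sigma0) shared
across samples, planted effects add ``effect_size`` to the log2 signal of
in-cluster samples, and replicate noise is Normal(0, noise_sd) on the log2
scale.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    MARKS,
    ROI_CLASSES,
    GenomicInterval,
    RegionSet,
    SignalTrack,
    StateSegmentation,
)

#: Archetype chromatin-state paths over (first, intermediate, last) stages.
#: Each archetype starts in a distinct state so that state diversity genuinely
#: collapses as differentiation proceeds (the entropy signature the state
#: dynamics module quantifies).
TRAJECTORY_PATHS = {
    "silencing": ("TssBiv", "ReprPC", "Quies"),
    "bivalent_retained": ("BivFlnk", "TssBiv", "TssBiv"),
    "early_activation": ("EnhBiv", "Enh", "Enh"),
    "late_activation": ("ReprPCWk", "Quies", "Enh"),
    "quiescent": ("Quies", "Quies", "Quies"),
}

#: Characteristic log2 mark levels per chromatin state (emission profile used
#: to derive per-stage signal tracks from a window's state).  Baseline 1.0 is
#: "unmarked"; active-promoter states are H3K4me3-high, enhancer states
#: H3K4me1-high, Polycomb states H3K27me3-high, heterochromatin H3K9me3-high.
STATE_MARK_PROFILE = {
    "TssA": {"H3K4me3": 6.0, "H3K4me1": 3.0},
    "TssAFlnk": {"H3K4me3": 4.0, "H3K4me1": 4.0},
    "TxFlnk": {"H3K4me1": 4.0, "H3K36me3": 4.0},
    "Tx": {"H3K36me3": 6.0},
    "TxWk": {"H3K36me3": 3.0},
    "EnhG": {"H3K4me1": 5.0, "H3K36me3": 4.0},
    "Enh": {"H3K4me1": 6.0},
    "ZNF/Rpts": {"H3K36me3": 4.0, "H3K9me3": 4.0},
    "Het": {"H3K9me3": 6.0},
    "TssBiv": {"H3K4me3": 5.0, "H3K27me3": 5.0},
    "BivFlnk": {"H3K4me3": 4.0, "H3K4me1": 4.0, "H3K27me3": 4.0},
    "EnhBiv": {"H3K4me1": 5.0, "H3K27me3": 5.0},
    "ReprPC": {"H3K27me3": 6.0},
    "ReprPCWk": {"H3K27me3": 3.0},
    "Quies": {},
}

_BASELINE_LOG2 = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth simulation.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 3 sample clusters of 4 samples, 2 replicates each, a 2 x 10 Mb toy
    genome, a log2 effect of 2.0 against replicate noise of 0.25, and one
    informative mark-ROI combination (H3K4me1 at lincRNA TSS windows).
    """

    n_clusters: int = 3
    samples_per_cluster: int = 4
    replicates_per_sample: int = 2
    n_regions: dict = field(default_factory=lambda: {c: 120 for c in ROI_CLASSES})
    frac_specific: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.25
    mu0: float = 3.0
    sigma0: float = 1.0
    genome: list = field(
        default_factory=lambda: [("chr1", 10_000_000), ("chr2", 10_000_000)]
    )
    stages: tuple = ("ESC", "HSC", "TCell")
    trajectory_mix: dict = field(
        default_factory=lambda: {
            "silencing": 0.40,
            "bivalent_retained": 0.15,
            "early_activation": 0.15,
            "late_activation": 0.15,
            "quiescent": 0.15,
        }
    )
    informative_combinations: list = field(
        default_factory=lambda: [("H3K4me1", "lincRNA_TSS")]
    )
    tss_window: int = 3000
    n_tfs: int = 12
    sites_per_tf: int = 150
    n_enriched_tfs: int = 3
    enriched_fraction: float = 0.6
    tf_site_width: int = 10
    seed: int = 7

    def validate(self) -> None:
        if self.n_clusters < 1 or self.samples_per_cluster < 1:
            raise ValueError("cluster and sample counts must be >= 1")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if not 0.0 <= self.frac_specific <= 1.0:
            raise ValueError("frac_specific must be in [0, 1]")
        for cls, n in self.n_regions.items():
            if n < 1:
                raise ValueError(f"zero regions requested for roi_class {cls}")
        total = sum(self.trajectory_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trajectory_mix sums to {total}, expected 1")
        unknown = set(self.trajectory_mix) - set(TRAJECTORY_PATHS)
        if unknown:
            raise ValueError(f"unknown trajectory classes: {sorted(unknown)}")

    def sample_ids(self) -> list[str]:
        return [
            f"C{c + 1}_S{s + 1}"
            for c in range(self.n_clusters)
            for s in range(self.samples_per_cluster)
        ]

    def cluster_of(self, sample_id: str) -> str:
        return sample_id.split("_")[0]

    def cluster_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids():
            out.setdefault(self.cluster_of(sid), []).append(sid)
        return out


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests.

    ``specific_regions`` maps (roi_class, mark, cluster_id) to the set of
    region names planted with in-cluster elevation; ``trajectory_class`` maps
    each TSS window name to its archetype; ``enriched_tfs`` names the factors
    planted with ROI-concentrated binding sites.
    """

    specific_regions: dict = field(default_factory=dict)
    trajectory_class: dict = field(default_factory=dict)
    enriched_tfs: set = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "specific_regions": {
                "|".join(k): sorted(v) for k, v in self.specific_regions.items()
            },
            "trajectory_class": self.trajectory_class,
            "enriched_tfs": sorted(self.enriched_tfs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            specific_regions={
                tuple(k.split("|")): set(v)
                for k, v in payload["specific_regions"].items()
            },
            trajectory_class=dict(payload["trajectory_class"]),
            enriched_tfs=set(payload["enriched_tfs"]),
        )


# ---------------------------------------------------------------------------
# Region layout
# ---------------------------------------------------------------------------

_REGION_WIDTHS = {
    "lincRNA_body": 5000,
    "lincRNA_TSS": None,  # tss_window, stranded
    "miRNA": 200,
    "gene_body": 8000,
    "exons": 300,
    "3UTR": 800,
    "promoter": None,  # tss_window, stranded
    "enhancer": 1000,
}


def make_region_sets(config: SimulationConfig) -> dict[str, RegionSet]:
    """Lay out non-overlapping region sets for every requested ROI class.

    Regions of all classes are interleaved along the toy genome with fixed
    gaps; TSS-window classes are stranded with alternating orientation.
    """
    config.validate()
    cursors = {chrom: 1000 for chrom, _ in config.genome}
    lengths = dict(config.genome)
    chrom_cycle = [chrom for chrom, _ in config.genome]
    out: dict[str, RegionSet] = {}
    ci = 0
    for roi_class in ROI_CLASSES:
        if roi_class not in config.n_regions:
            continue
        width = _REGION_WIDTHS[roi_class] or config.tss_window
        stranded = _REGION_WIDTHS[roi_class] is None
        intervals = []
        for i in range(config.n_regions[roi_class]):
            chrom = chrom_cycle[ci % len(chrom_cycle)]
            ci += 1
            start = cursors[chrom]
            if start + width + 500 > lengths[chrom]:
                raise ValueError(f"toy genome too small for requested regions ({roi_class})")
            cursors[chrom] = start + width + 500
            strand = ("+", "-")[i % 2] if stranded else "."
            intervals.append(
                GenomicInterval(chrom, start, start + width, f"{roi_class}_{i}", strand)
            )
        out[roi_class] = RegionSet(roi_class, intervals)
    return out


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------


def simulate_epigenomes(config: SimulationConfig):
    """Simulate per-replicate signal tracks for every sample and mark.

    Returns ``(tracks, region_sets, truth)`` where ``tracks`` maps
    (sample_id, replicate_id, mark) to a :class:`SignalTrack` that is
    piecewise-constant over the simulated regions (gaps are 0 signal).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    region_sets = make_region_sets(config)
    samples = config.sample_ids()
    clusters = config.cluster_members()
    truth = PlantedTruth()

    # per (roi_class, mark): region baselines and planted cluster assignment
    baselines: dict[tuple, np.ndarray] = {}
    planted: dict[tuple, dict[str, np.ndarray]] = {}
    for roi_class, regions in region_sets.items():
        n = len(regions)
        for mark in MARKS:
            baselines[(roi_class, mark)] = rng.normal(config.mu0, config.sigma0, size=n)
        for mark, roi in config.informative_combinations:
            if roi != roi_class:
                continue
            n_spec = int(round(config.frac_specific * n))
            perm = rng.permutation(n)
            offset = 0
            planted[(roi_class, mark)] = {}
            for cluster_id in clusters:
                idx = perm[offset : offset + n_spec]
                offset += n_spec
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                planted[(roi_class, mark)][cluster_id] = mask
                truth.specific_regions[(roi_class, mark, cluster_id)] = {
                    regions.names[i] for i in idx
                }

    tracks: dict[tuple, SignalTrack] = {}
    for sample in samples:
        cluster_id = config.cluster_of(sample)
        for mark in MARKS:
            # per-sample expected log2 signal over each region set
            expected = {}
            for roi_class, regions in region_sets.items():
                mu = baselines[(roi_class, mark)].copy()
                masks = planted.get((roi_class, mark))
                if masks is not None:
                    mu = mu + config.effect_size * masks[cluster_id]
                expected[roi_class] = mu
            for r in range(config.replicates_per_sample):
                rep_id = f"rep{r + 1}"
                rows = []
                for roi_class, regions in region_sets.items():
                    noise = rng.normal(0.0, config.noise_sd, size=len(regions))
                    vals = np.exp2(expected[roi_class] + noise)
                    for iv, v in zip(regions, vals):
                        rows.append((iv.chrom, iv.start, iv.end, float(v)))
                df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
                tracks[(sample, rep_id, mark)] = SignalTrack(sample, rep_id, mark, df)
    return tracks, region_sets, truth


# ---------------------------------------------------------------------------
# State trajectories
# ---------------------------------------------------------------------------


def _path_for_stages(class_name: str, n_stages: int) -> list[str]:
    first, mid, last = TRAJECTORY_PATHS[class_name]
    if n_stages == 2:
        return [first, last]
    return [first] + [mid] * (n_stages - 2) + [last]


def allocate_trajectory_classes(config: SimulationConfig, n_tss: int) -> list[str]:
    """Deterministic largest-remainder-free allocation: cumulative rounding of
    the mix proportions, in the mix's insertion order."""
    classes = list(config.trajectory_mix)
    props = np.array([config.trajectory_mix[c] for c in classes], dtype=float)
    bounds = np.round(np.cumsum(props) * n_tss).astype(int)
    counts = np.diff(np.concatenate([[0], bounds]))
    labels = []
    for cls, k in zip(classes, counts):
        labels.extend([cls] * int(k))
    return labels


def simulate_state_trajectories(config: SimulationConfig, tss: RegionSet | None = None):
    """Plant an archetype state path at every TSS window, per stage.

    Returns ``(segmentations, truth)``: one :class:`StateSegmentation` per
    stage covering each TSS window with its archetype's state at that stage.
    """
    config.validate()
    if len(config.stages) < 2:
        raise ValueError("need >= 2 stages for state trajectories")
    if tss is None:
        tss = make_region_sets(config)["lincRNA_TSS"]
    rng = np.random.default_rng(config.seed + 1)
    labels = allocate_trajectory_classes(config, len(tss))
    order = rng.permutation(len(tss))
    truth = PlantedTruth()
    assigned = [None] * len(tss)
    for pos, lab in zip(order, labels):
        assigned[pos] = lab
    for iv, lab in zip(tss, assigned):
        truth.trajectory_class[iv.name] = lab

    n_stages = len(config.stages)
    segmentations = []
    for si, stage in enumerate(config.stages):
        rows = [
            (iv.chrom, iv.start, iv.end, _path_for_stages(lab, n_stages)[si])
            for iv, lab in zip(tss, assigned)
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        segmentations.append(StateSegmentation(stage, stage, df))
    return segmentations, truth


def simulate_footprint_tracks(
    config: SimulationConfig, tss: RegionSet, truth: PlantedTruth
):
    """Derive per-(stage, mark) signal tracks from each window's state path.

    Each window emits its state's characteristic log2 mark levels
    (:data:`STATE_MARK_PROFILE`) plus Normal(0, noise_sd) log-scale noise,
    constant across the window.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_stages = len(config.stages)
    tracks: dict[tuple, SignalTrack] = {}
    for si, stage in enumerate(config.stages):
        states = [
            _path_for_stages(truth.trajectory_class[iv.name], n_stages)[si] for iv in tss
        ]
        for mark in MARKS:
            rows = []
            noise = rng.normal(0.0, config.noise_sd, size=len(tss))
            for iv, state, eps in zip(tss, states, noise):
                level = STATE_MARK_PROFILE[state].get(mark, _BASELINE_LOG2)
                rows.append((iv.chrom, iv.start, iv.end, float(np.exp2(level + eps))))
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
            tracks[(stage, mark)] = SignalTrack(stage, "rep1", mark, df)
    return tracks


# ---------------------------------------------------------------------------
# TF binding sites
# ---------------------------------------------------------------------------


def simulate_tfbs(config: SimulationConfig, roi: RegionSet):
    """Simulate per-factor binding-site sets with planted ROI enrichment.

    The first ``n_enriched_tfs`` factors place ``enriched_fraction`` of their
    sites inside ROI intervals; all other sites land uniformly on the genome.
    """
    config.validate()
    if len(roi) == 0:
        raise ValueError("roi must be non-empty")
    rng = np.random.default_rng(config.seed + 3)
    chroms = [c for c, _ in config.genome]
    lengths = dict(config.genome)
    w = config.tf_site_width
    truth = PlantedTruth()
    out: dict[str, RegionSet] = {}
    for t in range(config.n_tfs):
        tf = f"TF{t + 1}"
        enriched = t < config.n_enriched_tfs
        if enriched:
            truth.enriched_tfs.add(tf)
        intervals = []
        for s in range(config.sites_per_tf):
            if enriched and rng.random() < config.enriched_fraction:
                iv = roi.intervals[rng.integers(len(roi))]
                pos = iv.start + rng.integers(max(1, len(iv) - w))
                chrom = iv.chrom
            else:
                chrom = chroms[rng.integers(len(chroms))]
                pos = int(rng.integers(0, lengths[chrom] - w))
            intervals.append(GenomicInterval(chrom, pos, pos + w, f"{tf}_site{s}"))
        out[tf] = RegionSet("tfbs", intervals)
    return out, truth
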