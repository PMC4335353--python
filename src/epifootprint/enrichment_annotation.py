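"""TFBS enrichment, region-to-gene association and expression summaries.

TF binding-site enrichment follows a hypergeometric model whose background is
the pooled site set of *all* probed factors: with N total sites, n of them
overlapping the ROI (by >= 1 bp, each site counted once), a factor with K
sites of which k overlap is scored P(X >= k), X ~ Hypergeom(N, K, n).

Region-to-gene association uses the basal-plus-extension regulatory-domain
rule: each gene's basal domain spans 5 kb upstream to 1 kb downstream of its
TSS (strand-oriented); the domain then extends in both directions to the
nearest neighbouring basal-domain boundary, capped at 500 kb from the TSS,
and a region associates with every gene whose domain it overlaps by >= 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .footprint_clustering import FootprintClusters
from .io_formats import GenomicInterval, RegionSet
from .differential_marking import bh_fdr

logger = logging.getLogger(__name__)

DISTANCE_BINS = ("<5kb", "5-50kb", "50-500kb", ">500kb")


def _merged_intervals(regions: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping intervals per chromosome into sorted disjoint arrays."""
    out = {}
    by_chrom: dict[str, list] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps_any(iv: GenomicInterval, merged) -> bool:
    arrs = merged.get(iv.chrom)
    if arrs is None:
        return False
    starts, ends = arrs
    j = np.searchsorted(starts, iv.end, side="left")
    return j > 0 and ends[j - 1] > iv.start or (
        j < len(starts) and starts[j] < iv.end and ends[j] > iv.start
    )


def count_overlapping_sites(sites: RegionSet, roi: RegionSet) -> int:
    """Number of sites overlapping >= 1 bp of >= 1 ROI interval (each once)."""
    merged = _merged_intervals(roi)
    return sum(1 for iv in sites if _overlaps_any(iv, merged))


def tfbs_enrichment(roi: RegionSet, sites: dict[str, RegionSet]) -> pd.DataFrame:
    """Hypergeometric TFBS enrichment of each factor against the pooled
    all-factor background.

    Returns per factor: k, K, n, N, fold = (k/K)/(n/N), upper-tail p
    (survival function, numerically stable), and BH-adjusted p across factors.
    """
    if not sites:
        raise ValueError("need >= 1 TF site set")
    if len(roi) == 0:
        raise ValueError("ROI must be non-empty")
    merged = _merged_intervals(roi)
    per_tf = {}
    for tf, site_set in sites.items():
        if len(site_set) == 0:
            logger.warning("TF %s has zero sites; skipped", tf)
            continue
        k = sum(1 for iv in site_set if _overlaps_any(iv, merged))
        per_tf[tf] = (k, len(site_set))
    N = sum(K for _, K in per_tf.values())
    n = sum(k for k, _ in per_tf.values())
    rows = []
    for tf, (k, K) in per_tf.items():
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / K) / (n / N) if n > 0 else float("nan")
        rows.append({"tf": tf, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)


@dataclass
class GeneAssociation:
    """Region -> associated-gene map plus the rule parameters used."""

    associations: dict[str, set]
    basal_up: int
    basal_down: int
    max_ext: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "gene": g}
            for r, gs in self.associations.items()
            for g in sorted(gs)
        ]
        return pd.DataFrame(rows, columns=["region", "gene"])


def _regulatory_domains(
    genes: RegionSet, basal_up: int, basal_down: int, max_ext: int
) -> dict[str, list[tuple[int, int, str]]]:
    """Extended regulatory domain (start, end, gene) per chromosome."""
    by_chrom: dict[str, list] = {}
    for iv in genes:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"gene {iv.name} lacks strand")
        t = iv.tss()
        if iv.strand == "+":
            b_s, b_e = t - basal_up, t + basal_down
        else:
            b_s, b_e = t - basal_down + 1, t + basal_up + 1
        by_chrom.setdefault(iv.chrom, []).append((t, max(0, b_s), max(1, b_e), iv.name))
    domains: dict[str, list] = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        doms = []
        for i, (t, b_s, b_e, name) in enumerate(entries):
            prev_end = entries[i - 1][2] if i > 0 else 0
            next_start = entries[i + 1][1] if i + 1 < len(entries) else None
            ext_s = min(b_s, max(prev_end, t - max_ext))
            if next_start is None:
                ext_e = max(b_e, t + max_ext)
            else:
                ext_e = max(b_e, min(next_start, t + max_ext))
            doms.append((max(0, ext_s), ext_e, name))
        domains[chrom] = doms
    return domains


def associate_regions_to_genes(
    regions: RegionSet,
    genes: RegionSet,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 500_000,
) -> GeneAssociation:
    """Associate each region with every gene whose basal-plus-extension
    regulatory domain it overlaps by >= 1 bp."""
    domains = _regulatory_domains(genes, basal_up, basal_down, max_ext)
    associations: dict[str, set] = {}
    for iv in regions:
        hits = set()
        for ds, de, gene in domains.get(iv.chrom, ()):
            if ds < iv.end and de > iv.start:
                hits.add(gene)
        associations[iv.name] = hits
    return GeneAssociation(associations, basal_up, basal_down, max_ext)


@dataclass
class DistanceBinReport:
    """Counts of query TSSs by distance to the nearest gene TSS."""

    counts: dict[str, int]
    distances: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"bin": b, "n": self.counts.get(b, 0)} for b in DISTANCE_BINS]
        )


def distance_bins(query_tss: RegionSet, gene_tss: RegionSet) -> DistanceBinReport:
    """Absolute distance of each query TSS to the nearest gene TSS, binned
    [0, 5 kb), [5 kb, 50 kb), [50 kb, 500 kb]; beyond 500 kb is unassigned."""
    if len(query_tss) == 0 or len(gene_tss) == 0:
        raise ValueError("both TSS sets must be non-empty")
    gene_pos: dict[str, np.ndarray] = {}
    for iv in gene_tss:
        gene_pos.setdefault(iv.chrom, []).append(iv.tss())
    gene_pos = {c: np.sort(np.array(p)) for c, p in gene_pos.items()}
    counts = {b: 0 for b in DISTANCE_BINS}
    distances = {}
    for iv in query_tss:
        t = iv.tss()
        pos = gene_pos.get(iv.chrom)
        if pos is None:
            d = float("inf")
        else:
            j = np.searchsorted(pos, t)
            cand = []
            if j > 0:
                cand.append(abs(t - pos[j - 1]))
            if j < len(pos):
                cand.append(abs(pos[j] - t))
            d = float(min(cand))
        distances[iv.name] = d
        if d < 5_000:
            counts["<5kb"] += 1
        elif d < 50_000:
            counts["5-50kb"] += 1
        elif d <= 500_000:
            counts["50-500kb"] += 1
        else:
            counts[">500kb"] += 1
    return DistanceBinReport(counts, distances)


def expression_by_cluster(
    clusters: FootprintClusters,
    expression: pd.DataFrame,
    associations: GeneAssociation | None = None,
) -> pd.DataFrame:
    """Median and IQR of RPKM per footprint cluster.

    ``expression`` needs columns (name, rpkm).  With ``associations``, the
    summary additionally covers the genes associated with each cluster's
    elements.  Elements without expression are dropped and counted.
    """
    expr = dict(zip(expression["name"], expression["rpkm"]))
    rows = []
    for label in range(1, clusters.k + 1):
        members = clusters.members(label)
        vals = [expr[m] for m in members if m in expr]
        if associations is not None:
            gene_names = set()
            for m in members:
                gene_names |= associations.associations.get(m, set())
            gene_vals = [expr[g] for g in gene_names if g in expr]
        else:
            gene_vals = []
        for kind, v in (("element", vals), ("associated_gene", gene_vals)):
            if associations is None and kind == "associated_gene":
                continue
            arr = np.asarray(v, dtype=float)
            rows.append(
                {
                    "cluster": label,
                    "kind": kind,
                    "n": len(arr),
                    "n_missing": (len(members) - len(vals)) if kind == "element" else None,
                    "median_rpkm": float(np.median(arr)) if len(arr) else float("nan"),
                    "iqr_rpkm": (
                        float(np.percentile(arr, 75) - np.percentile(arr, 25))
                        if len(arr)
                        else float("nan")
                    ),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty or df[df["kind"] == "element"]["n"].sum() == 0:
        raise ValueError("expression table covers no assigned element")
    return df
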