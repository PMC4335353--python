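"""Genomic interval containers and readers/writers for the flat-file formats
the pipeline consumes.

All coordinates are 0-based half-open (the BED convention); 1-based inputs are
not supported.  The five core histone marks and the 15 chromatin-state
mnemonics of the Roadmap consortium model are fixed vocabularies; state
spellings vary in the wild (``RepPC`` vs ``ReprPC``), so segmentation reading
accepts a user-extensible alias table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: The five core histone modifications profiled in every reference epigenome.
MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3", "H3K36me3")

#: The eight region-of-interest classes sliced for signal.
ROI_CLASSES = (
    "lincRNA_body",
    "lincRNA_TSS",
    "miRNA",
    "gene_body",
    "exons",
    "3UTR",
    "promoter",
    "enhancer",
)

#: Region-set labels that are consumed but never sliced (TF binding-site sets,
#: gene TSS annotations).
AUX_REGION_CLASSES = ("tfbs", "gene_tss")

#: Canonical 15-state chromatin-state mnemonics, in canonical order.
CHROMHMM_STATES = (
    "TssA",
    "TssAFlnk",
    "TxFlnk",
    "Tx",
    "TxWk",
    "EnhG",
    "Enh",
    "ZNF/Rpts",
    "Het",
    "TssBiv",
    "BivFlnk",
    "EnhBiv",
    "ReprPC",
    "ReprPCWk",
    "Quies",
)

#: Default alias map for state spellings seen in the literature.
DEFAULT_STATE_ALIASES = {
    "RepPC": "ReprPC",
    "RepPCWk": "ReprPCWk",
    "ZNF_Rpts": "ZNF/Rpts",
}

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A flat file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant of its domain type."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional name/strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"interval {self.name}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval {self.name}: end {self.end} <= start {self.start}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"interval {self.name}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def tss(self) -> int:
        """Transcription start: ``start`` on '+', ``end - 1`` on '-'."""
        if self.strand == "-":
            return self.end - 1
        return self.start


def tss_window(interval: GenomicInterval, width: int) -> GenomicInterval:
    """Window of ``width`` bp centred on the interval's TSS: [TSS-w/2, TSS+w/2)."""
    t = interval.tss()
    half = width // 2
    return GenomicInterval(
        interval.chrom, max(0, t - half), t + width - half, interval.name, interval.strand
    )


def as_window(interval: GenomicInterval, width: int) -> GenomicInterval:
    """Interpret an interval as a TSS window of ``width`` bp.

    TSS region files often already hold the +/- w/2 windows; an interval of
    exactly ``width`` bp is used as-is, anything else is re-centred on its
    TSS via :func:`tss_window`.
    """
    if len(interval) == width:
        return interval
    return tss_window(interval, width)


@dataclass
class RegionSet:
    """An ordered, uniquely-named collection of intervals of one ROI class."""

    roi_class: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.roi_class not in ROI_CLASSES + AUX_REGION_CLASSES:
            raise ValidationError(
                f"unknown roi_class {self.roi_class!r}; expected one of "
                f"{ROI_CLASSES + AUX_REGION_CLASSES}"
            )
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate region names: {dup[:5]}")

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def _check_interval_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Sort by (chrom, start) and reject overlapping intervals per chromosome."""
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValidationError(
            f"{what}: interval {bad['chrom']}:{bad['start']}-{bad['end']} has end <= start"
        )
    same_chrom = df["chrom"].eq(df["chrom"].shift())
    overlap = same_chrom & (df["start"] < df["end"].shift())
    if overlap.any():
        bad = df[overlap].iloc[0]
        raise ValidationError(
            f"{what}: overlapping intervals on {bad['chrom']} near position {bad['start']}"
        )
    return df


@dataclass
class SignalTrack:
    """Per-replicate signal for one histone mark.

    ``data`` holds columns (chrom, start, end, value); intervals are sorted and
    non-overlapping within each chromosome and values are finite and >= 0.
    Gaps between intervals are implicitly signal 0.
    """

    sample_id: str
    replicate_id: str
    mark: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValidationError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        df = self.data[["chrom", "start", "end", "value"]].copy()
        vals = pd.to_numeric(df["value"])
        if not vals.map(lambda v: v == v and abs(v) != float("inf")).all():
            raise ValidationError(f"track {self.sample_id}/{self.replicate_id}: non-finite value")
        if (vals < 0).any():
            raise ValidationError(
                f"track {self.sample_id}/{self.replicate_id}: negative signal value"
            )
        self.data = _check_interval_frame(df, f"track {self.sample_id}/{self.replicate_id}")


@dataclass
class StateSegmentation:
    """Chromatin-state annotation of one epigenome at one developmental stage.

    ``data`` holds columns (chrom, start, end, state) with every base covered
    by at most one state; states come from the 15-mnemonic vocabulary.
    """

    sample_id: str
    stage_label: str
    data: pd.DataFrame

    def __post_init__(self):
        bad = set(self.data["state"]) - set(CHROMHMM_STATES)
        if bad:
            raise ValidationError(f"unknown chromatin states: {sorted(bad)}")
        self.data = _check_interval_frame(
            self.data[["chrom", "start", "end", "state"]].copy(),
            f"segmentation {self.sample_id}/{self.stage_label}",
        )


# ---------------------------------------------------------------------------
# BED / bedGraph / segmentation readers and writers
# ---------------------------------------------------------------------------


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path, roi_class: str) -> RegionSet:
    """Read a BED3/BED6 file into a :class:`RegionSet`.

    Missing name columns are auto-named ``<roi_class>_<index>``; a missing
    strand defaults to ``.``.
    """
    intervals = []
    for idx, (lineno, fields) in enumerate(_iter_data_lines(path)):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{roi_class}_{idx}"
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(GenomicInterval(fields[0], start, end, name, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(roi_class, intervals)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_bedgraph(path, sample_id: str, replicate_id: str, mark: str) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Input need not be sorted; overlapping intervals and negative values are
    rejected.
    """
    rows = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed coordinate or value") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(sample_id, replicate_id, mark, df)


def write_bedgraph(track: SignalTrack, path) -> None:
    track.data.to_csv(path, sep="\t", header=False, index=False)


def read_segmentation(
    path, stage_label: str, sample_id: str = "", aliases: dict[str, str] | None = None
) -> StateSegmentation:
    """Read a 4-column dense segmentation BED whose name column is a state.

    ``aliases`` extends :data:`DEFAULT_STATE_ALIASES` (e.g. ``RepPC → ReprPC``).
    """
    alias_map = dict(DEFAULT_STATE_ALIASES)
    if aliases:
        alias_map.update(aliases)
    rows = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 segmentation columns")
        state = alias_map.get(fields[3], fields[3])
        if state not in CHROMHMM_STATES:
            raise ValidationError(
                f"{path}:{lineno}: unknown chromatin state {fields[3]!r} "
                f"(no alias; known states: {', '.join(CHROMHMM_STATES)})"
            )
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), state))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return StateSegmentation(sample_id, stage_label, df)


def write_segmentation(seg: StateSegmentation, path) -> None:
    seg.data.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree) -> str:
    """Serialize a :class:`~epifootprint.tree_concordance.Dendrogram` to Newick.

    Branch lengths are parent height minus child height (leaves at height 0).
    """

    def fmt(node, parent_height):
        length = parent_height - node.height
        suffix = f":{length:.10g}" if parent_height is not None else ""
        if not node.children:
            return f"{node.label}{suffix}" if parent_height is not None else f"{node.label}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}){suffix}"

    def fmt_root(node):
        if not node.children:
            return str(node.label)
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner})"

    return fmt_root(tree.root) + ";"


def read_newick(text: str):
    """Parse a Newick string into a Dendrogram (heights from leaf depths)."""
    from .tree_concordance import Dendrogram, TreeNode

    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode):
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(label=label, height=0.0)
        children = [convert(c) for c in dnode.child_nodes()]
        height = max(
            c.height + (d.edge.length if d.edge.length is not None else 1.0)
            for c, d in zip(children, dnode.child_nodes())
        )
        return TreeNode(children=children, height=height)

    return Dendrogram(convert(dtree.seed_node))
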