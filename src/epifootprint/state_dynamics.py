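"""Chromatin-state assignment at TSS windows and stage-to-stage dynamics.

Each TSS window gets the 15-state label covering the most bases of the window
(majority overlap; canonical-order tie break; uncovered windows are Quies).
Counting windows over consecutive stage pairs gives 15 x 15 transition
matrices (225 cells), row-normalized to per-source-state proportions; edges
above a proportion threshold (default 30%) form the reportable transition
graph.  Shannon entropy of the per-stage state distribution quantifies the
loss of combinatorial chromatin diversity during differentiation, computed
for all states and separately inside/outside the Polycomb-associated subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CHROMHMM_STATES, GenomicInterval, RegionSet, StateSegmentation

#: Polycomb-associated states: the bivalent flavours plus the two
#: Polycomb-repressed states (H3K27me3-mediated).
POLYCOMB_STATES = ("TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk")


def assign_state(
    segmentation: StateSegmentation, window: GenomicInterval, point: bool = False
) -> str:
    """State of a window: majority base overlap (default) or point lookup.

    Ties break by canonical 15-state order; zero coverage falls back to Quies.
    With ``point=True`` the state at the TSS midpoint of the window is used.
    """
    df = segmentation.data
    sub = df[df["chrom"] == window.chrom]
    if point:
        mid = (window.start + window.end) // 2
        hit = sub[(sub["start"] <= mid) & (sub["end"] > mid)]
        return hit["state"].iloc[0] if len(hit) else "Quies"
    ov = np.minimum(sub["end"], window.end) - np.maximum(sub["start"], window.start)
    cover = {}
    for state, bases in zip(sub["state"], ov):
        if bases > 0:
            cover[state] = cover.get(state, 0) + int(bases)
    if not cover:
        return "Quies"
    best = max(cover.values())
    for state in CHROMHMM_STATES:  # canonical-order tie break
        if cover.get(state) == best:
            return state
    raise AssertionError("unreachable")


def assign_states(
    segmentation: StateSegmentation, windows: RegionSet, point: bool = False
) -> dict[str, str]:
    """Vectorized-enough wrapper: window name -> state for a whole region set."""
    return {iv.name: assign_state(segmentation, iv, point=point) for iv in windows}


@dataclass
class StateTransitionMatrix:
    """15 x 15 window counts for one stage pair, plus row-normalized form."""

    stage_from: str
    stage_to: str
    counts: pd.DataFrame
    row_normalized: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.counts.size


def transition_counts(
    assign_a: dict[str, str],
    assign_b: dict[str, str],
    stage_from: str = "A",
    stage_to: str = "B",
) -> StateTransitionMatrix:
    """Count windows by (state at stage A, state at stage B)."""
    if set(assign_a) != set(assign_b):
        missing = set(assign_a) ^ set(assign_b)
        raise ValueError(f"TSS universes differ between stages: {sorted(missing)[:5]}")
    states = list(CHROMHMM_STATES)
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((15, 15), dtype=int)
    for name, sa in assign_a.items():
        counts[idx[sa], idx[assign_b[name]]] += 1
    counts_df = pd.DataFrame(counts, index=states, columns=states)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, 0.0)
    norm_df = pd.DataFrame(norm, index=states, columns=states)
    return StateTransitionMatrix(stage_from, stage_to, counts_df, norm_df)


def filter_transitions(
    matrix: StateTransitionMatrix, threshold: float = 0.30
) -> pd.DataFrame:
    """Edges with row-normalized proportion strictly above ``threshold``."""
    rows = []
    norm = matrix.row_normalized
    for s in norm.index:
        for t in norm.columns:
            prop = float(norm.loc[s, t])
            if prop > threshold:
                rows.append(
                    {
                        "from_state": s,
                        "to_state": t,
                        "proportion": prop,
                        "count": int(matrix.counts.loc[s, t]),
                    }
                )
    return pd.DataFrame(rows, columns=["from_state", "to_state", "proportion", "count"])


def state_entropy(
    assignment: dict[str, str],
    subset: tuple[str, ...] | None = None,
    renormalize: bool = True,
) -> float:
    """Shannon entropy (bits) of the state distribution at one stage.

    With ``subset``, windows outside the subset states are dropped and the
    distribution renormalized within the subset (default), or the partial
    distribution is used as-is (``renormalize=False``).  Empty occupancy of a
    subset yields 0.
    """
    if not assignment:
        raise ValueError("need >= 1 assigned window")
    states = list(assignment.values())
    if subset is not None:
        states = [s for s in states if s in set(subset)]
        if not states:
            return 0.0
    counts = pd.Series(states).value_counts()
    p = counts.to_numpy(dtype=float)
    p = p / (len(assignment) if (subset is not None and not renormalize) else p.sum())
    return float(max(-(p * np.log2(p)).sum(), 0.0))  # avoid -0.0


@dataclass
class EntropyReport:
    """Per-stage entropies over all, Polycomb, and non-Polycomb states."""

    stages: list[str]
    h_all: list[float]
    h_polycomb: list[float]
    h_nonpolycomb: list[float]
    polycomb_states: tuple[str, ...] = POLYCOMB_STATES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stages,
                "H_all_bits": self.h_all,
                "H_polycomb_bits": self.h_polycomb,
                "H_nonpolycomb_bits": self.h_nonpolycomb,
            }
        )


def entropy_report(
    assignments: list[dict[str, str]],
    stages: list[str],
    polycomb_states: tuple[str, ...] = POLYCOMB_STATES,
) -> EntropyReport:
    non_pc = tuple(s for s in CHROMHMM_STATES if s not in set(polycomb_states))
    return EntropyReport(
        stages=list(stages),
        h_all=[state_entropy(a) for a in assignments],
        h_polycomb=[state_entropy(a, subset=polycomb_states) for a in assignments],
        h_nonpolycomb=[state_entropy(a, subset=non_pc) for a in assignments],
        polycomb_states=tuple(polycomb_states),
    )
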