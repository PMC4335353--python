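"""Empirical-Bayes moderated two-group testing of histone-mark signal.

For each region of a (log2-transformed, quantile-normalized) data slice, the
signal is regressed on an intercept plus an in-cluster indicator; the residual
variance s^2 (d = n - 2 df) is shrunk toward a prior estimated from the
across-region distribution of s^2 by moment matching on log s^2, giving the
moderated t statistic

    t_mod = effect / (s_tilde * sqrt(1/n1 + 1/n2)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

with d + d0 degrees of freedom.  This is the standard moderated-t model for
small-sample genomic comparisons, authored here rather than delegated.

Regions are then classified by how many clusters mark them (in any histone
mark) at BH FDR < alpha: unique (1), shared_2_3 (2-3), nonspecific_marked
(>= 4), unmarked (0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .slicing import DataSlice

logger = logging.getLogger(__name__)

SPECIFICITY_CLASSES = ("unique", "shared_2_3", "nonspecific_marked", "unmarked")


@dataclass
class ClusterDefinition:
    """A sample cluster (tree clade) and its optional related-cluster group."""

    cluster_id: str
    members: list[str]
    group_id: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to observed residual variances.

    Works on z = log(s2): E[z] and Var[z] relate to (d0, s0^2) through digamma
    and trigamma functions.  Returns (inf, geometric-mean variance) when the
    observed spread is no wider than sampling noise (full shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        logger.info("variance spread within sampling noise; full shrinkage (d0=inf)")
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_two_group_test(
    slice_: DataSlice,
    cluster: ClusterDefinition,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t test of in-cluster vs out-of-cluster samples per region.

    ``slice_`` must already be log2-transformed (and normally quantile
    normalized).  ``prior_df`` overrides the estimated d0; 0 disables
    moderation (classical pooled-variance t), inf forces full shrinkage.

    Returns a DataFrame with columns region, cluster, mark, effect, t_mod,
    df_total, p, fdr, significant, constant.
    """
    in_ids = [s for s in slice_.sample_ids if s in set(cluster.members)]
    out_ids = [s for s in slice_.sample_ids if s not in set(cluster.members)]
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValueError(
            f"cluster {cluster.cluster_id}: need >= 2 samples per group "
            f"(got {len(in_ids)} vs {len(out_ids)})"
        )
    col = {s: j for j, s in enumerate(slice_.sample_ids)}
    X = slice_.values
    A = X[:, [col[s] for s in in_ids]]
    B = X[:, [col[s] for s in out_ids]]
    n1, n2 = A.shape[1], B.shape[1]
    df_resid = n1 + n2 - 2
    effect = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    constant = (s2 == 0) & (effect == 0)

    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2[~constant], df_resid)
    else:
        d0 = float(prior_df)
        s02 = estimate_variance_prior(s2[~constant], df_resid)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # all-constant regions carry no evidence
    effect = np.where(constant, 0.0, effect)
    t_mod = np.where(constant, 0.0, t_mod)
    p = np.where(constant, 1.0, p)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "region": slice_.region_names,
            "cluster": cluster.cluster_id,
            "mark": slice_.mark,
            "effect": effect,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
            "constant": constant,
        }
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SpecificityAssignment:
    """Per-region marked-cluster sets and the resulting specificity class."""

    marked_clusters: dict[str, frozenset]
    classes: dict[str, str]

    def summary(self) -> pd.DataFrame:
        """Class percentages under both denominators: all regions, and
        regions marked in at least one cluster."""
        n_total = len(self.classes)
        n_marked = sum(1 for c in self.classes.values() if c != "unmarked")
        rows = []
        for cls in SPECIFICITY_CLASSES:
            k = sum(1 for c in self.classes.values() if c == cls)
            rows.append(
                {
                    "class": cls,
                    "n": k,
                    "pct_of_all": 100.0 * k / n_total if n_total else 0.0,
                    "pct_of_marked": (
                        100.0 * k / n_marked if n_marked and cls != "unmarked" else 0.0
                    ),
                }
            )
        return pd.DataFrame(rows)


def classify_specificity(
    results: pd.DataFrame,
    alpha: float = 0.05,
    clusters: list[ClusterDefinition] | None = None,
    strict_groups: bool = False,
) -> SpecificityAssignment:
    """Classify regions by the number of clusters marking them in any mark.

    1 cluster -> unique; 2-3 -> shared_2_3; >= 4 -> nonspecific_marked;
    0 -> unmarked.  With ``strict_groups``, shared_2_3 additionally requires
    the marking clusters to share a group_id (related subtrees); otherwise
    such regions fall to nonspecific_marked.
    """
    required = {"region", "cluster", "fdr"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    universes = results.groupby("cluster")["region"].apply(frozenset)
    if len(set(universes)) != 1:
        raise ValueError("inconsistent region universes across clusters")
    group_of = {}
    if clusters is not None:
        group_of = {c.cluster_id: c.group_id for c in clusters}

    sig = results[results["fdr"] < alpha]
    marked: dict[str, set] = {r: set() for r in universes.iloc[0]}
    for region, cluster in zip(sig["region"], sig["cluster"]):
        marked[region].add(cluster)

    classes = {}
    for region, cl_set in marked.items():
        k = len(cl_set)
        if k == 0:
            classes[region] = "unmarked"
        elif k == 1:
            classes[region] = "unique"
        elif k <= 3:
            if strict_groups:
                groups = {group_of.get(c) for c in cl_set}
                related = len(groups) == 1 and None not in groups
                classes[region] = "shared_2_3" if related else "nonspecific_marked"
            else:
                classes[region] = "shared_2_3"
        else:
            classes[region] = "nonspecific_marked"
    return SpecificityAssignment(
        {r: frozenset(s) for r, s in marked.items()}, classes
    )
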