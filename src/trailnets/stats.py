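"""Objectives, percentile comparison, and the nonparametric battery.

Each trail network is scored on four objectives: average edge length (cm),
total number of nodes, average transition index, and total edge length (cm).
An observed (or optimized) network is compared to a random ensemble through
its percentile: 100 x (fraction of random networks whose objective value is
less than or equal to the observed value).  A percentile of 50 means the
network does as well as the median random network; lower is better.

Because total length and total nodes are strongly positively correlated,
the statistical battery (Friedman across objectives, Conover-Iman post hoc)
uses only the three uncorrelated objectives: average edge length, total
nodes, and average transition index.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from trailnets.core import TrailNetwork, VegetationMap, transitions_of

logger = logging.getLogger(__name__)

#: objectives entering the Friedman/Conover battery (total_length excluded
#: because it is positively correlated with total_nodes)
BATTERY_OBJECTIVES = ("avg_edge_length", "total_nodes", "avg_ti")


@dataclass(frozen=True)
class ObjectiveVector:
    """The four objective values of one trail network.

    ``avg_ti`` is None for networks with no transitions (e.g. a single
    edge); such networks are excluded from TI percentiles.
    """

    avg_edge_length: Optional[float]
    total_nodes: float
    avg_ti: Optional[float]
    total_length: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "avg_edge_length": self.avg_edge_length,
            "total_nodes": self.total_nodes,
            "avg_ti": self.avg_ti,
            "total_length": self.total_length,
        }

    def __getitem__(self, key: str) -> Optional[float]:
        return self.as_dict()[key]


def compute_objectives(network: TrailNetwork, vmap: VegetationMap) -> ObjectiveVector:
    """Score one network on all four objectives."""
    lengths = [vmap.edges[eid].length for eid in network.edge_ids]
    trans = transitions_of(network.edge_ids, vmap) if network.edge_ids else []
    tis = [ti for _, _, _, ti in trans]
    return ObjectiveVector(
        avg_edge_length=sum(lengths) / len(lengths) if lengths else None,
        total_nodes=float(len(network.node_ids)),
        avg_ti=sum(tis) / len(tis) if tis else None,
        total_length=sum(lengths) if lengths else None,
    )


def percentile(observed: float, ensemble: Sequence[float]) -> float:
    """Percentage of ensemble values less than or equal to the observed value.

    ``100 x |{phi_i <= phi_obs}| / n``; ties count.  Lower percentiles mean
    the observed network optimizes the objective better than random.
    """
    vals = np.asarray([v for v in ensemble if v is not None], dtype=float)
    if vals.size == 0:
        raise ValueError("percentile of an empty ensemble is undefined")
    if observed is None:
        raise ValueError("observed value is undefined")
    return 100.0 * float(np.count_nonzero(vals <= observed)) / vals.size


def comparison_differences(records: pd.DataFrame) -> pd.DataFrame:
    """Paired difference vectors for observed-vs-random and observed-vs-
    optimized comparisons, in percentage points.

    Input columns: ``pct_obs`` and ``pct_opt``.  Adds ``d_rand = 50 -
    pct_obs`` (distance from the median random network) and ``d_opt =
    pct_obs - pct_opt`` (distance from the optimized network).
    """
    out = records.copy()
    out["d_rand"] = 50.0 - out["pct_obs"]
    out["d_opt"] = out["pct_obs"] - out["pct_opt"]
    return out


def wilcoxon_paired(
    d_rand: Sequence[float], d_opt: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of the paired difference vectors.

    Tests whether observed networks sit closer to the optimized network
    than to the median random network.  Degenerate all-zero differences
    return (0, 1).
    """
    a = np.asarray(d_rand, dtype=float)
    b = np.asarray(d_opt, dtype=float)
    if a.shape != b.shape:
        raise ValueError("difference vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    res = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_one_sample(d: Sequence[float]) -> tuple[float, float]:
    """One-sample signed-rank variant: is the difference vector centred on 0?"""
    a = np.asarray(d, dtype=float)
    if np.allclose(a, 0):
        return 0.0, 1.0
    res = sps.wilcoxon(a, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def friedman(matrix) -> tuple[float, float]:
    """Friedman chi-square across treatments (columns) with blocks (rows).

    For the observed-vs-random comparison the treatments are the three
    uncorrelated objectives and the blocks are colonies (day-averaged
    percentiles); transposing the matrix tests for colony differences
    instead.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    b, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 treatments")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    R = ranks.sum(axis=0)
    A1 = float((ranks**2).sum())
    C1 = b * k * (k + 1) ** 2 / 4.0
    if A1 - C1 <= 0:  # every block fully tied
        return 0.0, 1.0
    # tie-corrected Friedman chi-square (reduces to the classic
    # 12/(bk(k+1)) * sum R_j^2 - 3b(k+1) form without ties)
    q = (k - 1) * float(((R - b * (k + 1) / 2.0) ** 2).sum()) / (A1 - C1)
    p = float(sps.chi2.sf(q, k - 1))
    return float(q), p


def conover_iman(matrix, labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Conover-Iman pairwise post-hoc comparisons after a Friedman test.

    Uses the rank-sum t formulation: within each block the treatments are
    ranked; for treatments i, j the statistic is

        T = (R_i - R_j) / sqrt(2 b (A1 - C1) (1 - T1/(b(k-1))) / ((b-1)(k-1)))

    with R the rank sums, A1 the sum of squared ranks, C1 = b k (k+1)^2/4
    and T1 the (tie-corrected) Friedman statistic; T is referred to a t
    distribution with (b-1)(k-1) degrees of freedom.  p-values are two-sided
    and Bonferroni-corrected over the k(k-1)/2 pairs.
    """
    m = np.asarray(matrix, dtype=float)
    b, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 treatments")
    if labels is None:
        labels = [f"T{j+1}" for j in range(k)]
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    R = ranks.sum(axis=0)
    A1 = float((ranks**2).sum())
    C1 = b * k * (k + 1) ** 2 / 4.0
    df = (b - 1) * (k - 1)
    n_pairs = k * (k - 1) // 2
    rows = []
    if A1 - C1 <= 0:  # all blocks identical rankings impossible; all tied
        for i, j in itertools.combinations(range(k), 2):
            rows.append((labels[i], labels[j], 0.0, 1.0, 1.0))
        return pd.DataFrame(rows, columns=["a", "b", "T", "p_raw", "p_bonferroni"])
    T1 = (k - 1) * float(((R - b * (k + 1) / 2.0) ** 2).sum()) / (A1 - C1)
    scale = 1.0 - T1 / (b * (k - 1))
    denom2 = 2.0 * b * (A1 - C1) * scale / df
    for i, j in itertools.combinations(range(k), 2):
        if denom2 <= 0:
            t = math.inf if R[i] != R[j] else 0.0
        else:
            t = (R[i] - R[j]) / math.sqrt(denom2)
        p = 2.0 * sps.t.sf(abs(t), df) if df > 0 else float("nan")
        rows.append((labels[i], labels[j], float(t), p, min(1.0, p * n_pairs)))
    return pd.DataFrame(rows, columns=["a", "b", "T", "p_raw", "p_bonferroni"])


def objective_correlations(vectors: Iterable[ObjectiveVector]) -> pd.DataFrame:
    """All six pairwise Spearman correlations among the four objectives.

    Pairs with a constant (or insufficient) series are reported with R and
    p missing.
    """
    df = pd.DataFrame([v.as_dict() for v in vectors])
    if len(df) < 5:
        raise ValueError("need at least 5 networks")
    rows = []
    names = list(df.columns)
    for a, b in itertools.combinations(names, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 5 or sub[a].nunique() <= 1 or sub[b].nunique() <= 1:
            rows.append((a, b, np.nan, np.nan, len(sub)))
            continue
        r, p = sps.spearmanr(sub[a], sub[b])
        rows.append((a, b, float(r), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["a", "b", "spearman_r", "p", "n"])


def aggregate_percentiles(records: pd.DataFrame, value: str = "pct_obs") -> pd.DataFrame:
    """Mean percentile per colony x objective, averaging over observation
    days (one value per colony enters downstream tests, guarding against
    pseudoreplication)."""
    return (
        records.groupby(["colony", "objective"])[value]
        .mean()
        .unstack("objective")
    )
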