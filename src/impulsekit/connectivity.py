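"""Node-wise functional-connectivity screens.

Per animal (and treatment) a node x node Pearson correlation matrix is
computed from the node time series.  Two screens rank nodes:

* group difference: the mean correlation matrices of the HI and LI groups
  are subtracted and, for every node, the off-diagonal entries of its row of
  the difference matrix are tested against 0 with a one-sample t test
  (Bonferroni-corrected across nodes, ranked by |t|, sign positive when HI
  couples more strongly);
* treatment x group interaction: per node, node strength (mean off-diagonal
  correlation of that node) is the dependent variable of a two-way
  repeated-measures ANOVA with treatment as the within-subject factor and
  trait group between subjects; nodes are ranked by the interaction F.

Correlation matrices are averaged on the raw r scale by default (Fisher-z
averaging available); the mixed ANOVA is computed from sums of squares for
the balanced one-within/one-between design and vectorized across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NodeTimeseriesSet

__all__ = [
    "ConnectivityMatrix",
    "node_correlation_matrix",
    "node_strength",
    "group_mean_matrix",
    "group_difference_node_scores",
    "interaction_node_scores",
    "node_strength_table",
    "mixed_anova_interaction",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def node_correlation_matrix(series: np.ndarray,
                            node_names: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of one animal-treatment node series.

    ``series`` is (n_nodes, n_timepoints) with at least 3 time points;
    constant node series make the correlation undefined and raise an error
    listing the offending nodes.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("need a (nodes, time) array with >= 3 time points")
    names = tuple(node_names) if node_names is not None else tuple(
        f"node{i:02d}" for i in range(x.shape[0]))
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant node series: {bad}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, node_names=names)


def node_strength(matrix: ConnectivityMatrix, node: int | str) -> float:
    """Mean off-diagonal connectivity of one node."""
    i = (matrix.node_names.index(node) if isinstance(node, str) else int(node))
    row = np.delete(matrix.values[i], i)
    return float(row.mean())


def group_mean_matrix(matrices: Sequence[ConnectivityMatrix],
                      fisher: bool = False) -> np.ndarray:
    """Element-wise mean of correlation matrices (optionally via Fisher z)."""
    stack = np.stack([m.values for m in matrices])
    if fisher:
        z = np.arctanh(np.clip(stack, -0.999999, 0.999999))
        out = np.tanh(z.mean(axis=0))
        np.fill_diagonal(out, 1.0)
        return out
    return stack.mean(axis=0)


def group_difference_node_scores(matrices_hi: Sequence[ConnectivityMatrix],
                                 matrices_li: Sequence[ConnectivityMatrix],
                                 fisher: bool = False,
                                 variant: str = "group_mean") -> pd.DataFrame:
    """Node-wise t screen of the HI-minus-LI connectivity difference.

    The default ``variant="group_mean"`` follows the group-mean design: the
    group-mean matrices are subtracted and, for each node, the off-diagonal
    entries of its row of the difference are tested against 0 with a
    one-sample t.  Because those entries share the group-mean sampling
    noise they are not independent, so this screen's p values are
    descriptive (ranking device) rather than calibrated error rates; the
    ``variant="per_animal"`` sensitivity screen (two-sample t across
    animals on per-animal node strength) is calibrated under the null.

    Bonferroni correction multiplies the raw p by the node count;
    ``t_normalized`` divides by the maximum |t| (display ranking only).
    Rank 1 is the largest |t|; positive t means stronger coupling in HI.
    """
    if len(matrices_hi) < 2 or len(matrices_li) < 2:
        raise ValueError("each group needs at least 2 animals")
    names = matrices_hi[0].node_names
    n = len(names)
    tvals = np.empty(n)
    pvals = np.empty(n)
    if variant == "group_mean":
        diff = (group_mean_matrix(matrices_hi, fisher)
                - group_mean_matrix(matrices_li, fisher))
        for i in range(n):
            row = np.delete(diff[i], i)
            if np.allclose(row, row[0]):
                # zero-variance row: identical means give t = 0 exactly
                tvals[i] = 0.0 if np.allclose(row, 0.0) else np.inf * np.sign(row[0])
                pvals[i] = 1.0 if tvals[i] == 0.0 else 0.0
                continue
            res = stats.ttest_1samp(row, 0.0)
            tvals[i], pvals[i] = res.statistic, res.pvalue
    elif variant == "per_animal":
        def strengths(mats):
            s = np.stack([m.values for m in mats]).copy()
            for k in range(n):
                s[:, k, k] = np.nan
            return np.nanmean(s, axis=2)        # (animals, nodes)

        hi, li = strengths(matrices_hi), strengths(matrices_li)
        for i in range(n):
            res = stats.ttest_ind(hi[:, i], li[:, i])
            tvals[i], pvals[i] = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    return _score_table(names, tvals, pvals, statistic_name="t")


def _score_table(names, statvals, pvals, statistic_name: str) -> pd.DataFrame:
    n = len(names)
    bonf = np.minimum(pvals * n, 1.0)
    order = np.argsort(-np.abs(statvals), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    denom = np.max(np.abs(statvals))
    return pd.DataFrame({
        "node": list(names),
        "statistic": statvals,
        "statistic_name": statistic_name,
        f"{statistic_name}_normalized": statvals / denom if denom > 0 else statvals,
        "p_raw": pvals,
        "p_bonferroni": bonf,
        "rank": rank,
    })


# ---------------------------------------------------------------------------
# Treatment x group interaction screen
# ---------------------------------------------------------------------------

def node_strength_table(data: NodeTimeseriesSet) -> pd.DataFrame:
    """Per animal x treatment node strengths (long format)."""
    rows = []
    for (animal, treatment), series in data.series.items():
        m = node_correlation_matrix(series, data.node_names)
        v = m.values.copy()
        np.fill_diagonal(v, np.nan)
        strength = np.nanmean(v, axis=1)
        for name, s in zip(data.node_names, strength):
            rows.append({"animal_id": animal, "treatment": treatment,
                         "group": data.groups[animal], "node": name,
                         "strength": float(s)})
    return pd.DataFrame(rows)


def mixed_anova_interaction(y: np.ndarray, group_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interaction F and p of a balanced one-within/one-between mixed ANOVA.

    ``y`` is (n_subjects, n_within_levels[, n_nodes]); ``group_idx`` assigns
    each subject to one of two between groups.  The interaction mean square
    is tested against the within-by-subject error term.  Vectorized over a
    trailing nodes axis when present.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
        squeeze = True
    else:
        squeeze = False
    n_sub, b, _ = y.shape
    groups = np.unique(group_idx)
    a = len(groups)
    if a < 2:
        raise ValueError("both groups must be represented")
    grand = y.mean(axis=(0, 1))                       # (nodes,)
    m_t = y.mean(axis=0)                              # (b, nodes)
    ss_inter = np.zeros_like(grand)
    ss_err = np.zeros_like(grand)
    for g in groups:
        sel = group_idx == g
        n_g = int(sel.sum())
        if n_g < 2:
            raise ValueError("each group needs at least 2 subjects")
        yg = y[sel]                                   # (n_g, b, nodes)
        m_g = yg.mean(axis=(0, 1))                    # (nodes,)
        m_gt = yg.mean(axis=0)                        # (b, nodes)
        m_gs = yg.mean(axis=1)                        # (n_g, nodes)
        ss_inter += n_g * ((m_gt - m_g[None] - m_t + grand[None]) ** 2).sum(axis=0)
        resid = yg - m_gs[:, None, :] - m_gt[None] + m_g[None, None]
        ss_err += (resid ** 2).sum(axis=(0, 1))
    df_inter = (a - 1) * (b - 1)
    df_err = (b - 1) * (n_sub - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_inter / df_inter) / (ss_err / df_err)
    # degenerate designs with zero error variance: F is 0 unless the
    # interaction sum of squares itself is nonzero
    f = np.where(ss_err == 0, np.where(ss_inter == 0, 0.0, np.inf), f)
    p = stats.f.sf(f, df_inter, df_err)
    if squeeze:
        return float(f[0]), float(p[0])
    return f, p


def interaction_node_scores(strengths: pd.DataFrame,
                            group_labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Node-wise treatment x group repeated-measures interaction screen.

    ``strengths`` is the long table from :func:`node_strength_table`
    (columns ``animal_id, treatment, group, node, strength``); every animal
    must appear under every treatment level (missing cells raise an error
    naming the animal).  Returns a score table ranked by interaction F with
    Bonferroni-corrected p values.
    """
    df = strengths.copy()
    if group_labels is not None:
        df["group"] = df["animal_id"].map(dict(group_labels))
    treatments = sorted(df["treatment"].unique())
    nodes = list(dict.fromkeys(df["node"]))
    animals = sorted(df["animal_id"].unique())
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatment levels")
    # completeness check
    for animal in animals:
        have = set(df.loc[df["animal_id"] == animal, "treatment"])
        if have != set(treatments):
            missing = sorted(set(treatments) - have)
            raise ValueError(f"animal {animal!r} missing treatment cell(s): "
                             f"{missing}")
    group_of = df.drop_duplicates("animal_id").set_index("animal_id")["group"]
    group_idx = group_of.loc[animals].to_numpy()
    wide = df.pivot_table(index=["animal_id", "treatment"], columns="node",
                          values="strength", sort=False)
    y = np.empty((len(animals), len(treatments), len(nodes)))
    for i, animal in enumerate(animals):
        for j, tr in enumerate(treatments):
            y[i, j] = wide.loc[(animal, tr), nodes].to_numpy()
    f, p = mixed_anova_interaction(y, group_idx)
    return _score_table(tuple(nodes), f, p, statistic_name="F")
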