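"""Two-color loop-design microarray analysis.

In a loop design each array co-hybridizes two samples labeled Cy5 and Cy3,
and the samples form a connected graph (canonically a cycle), so every
pairwise contrast is estimable from few arrays.  The per-probe measurement
on array *a* is the log2 channel ratio

    M_a = log2(Cy5_a / Cy3_a) = mu[cy5(a)] - mu[cy3(a)] + dye/noise terms,

where mu is the per-sample log2 expression effect of the probe's transcript.
Analysis proceeds as: replicate averaging -> per-array global median
normalization (absorbing dye/offset effects) -> constrained least squares on
the design graph, minimizing sum_a (M_a - (mu_cy5(a) - mu_cy3(a)))^2 subject
to sum(mu) = 0.  The constrained minimizer is the Moore-Penrose solution
because the design matrix's null space is exactly the constant vector on a
connected design.

Downstream calls: a transcript is "distinct" when its maximal pairwise
|Delta mu| strictly exceeds tau_fold = 1 log2 unit (>2-fold), and
"predominant"/"depleted" in a focal sample when the focal effect beats (or
trails) every other sample by a margin.  Expression patterns are clustered
with average linkage on 1 - Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class DesignError(ValueError):
    """Raised for disconnected or underdetermined loop designs."""


# ---------------------------------------------------------------------------
# Experiment container
# ---------------------------------------------------------------------------

@dataclass
class LoopDesignExperiment:
    """Design plus the per-(array, probe) log-ratio matrix M."""

    samples: Tuple[str, ...]
    arrays: List[Tuple[str, str, str]]  # (array_id, cy5_sample, cy3_sample)
    M: pd.DataFrame  # index: array_id, columns: probe_id

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise DesignError("a loop design needs at least two samples")
        for _, cy5, cy3 in self.arrays:
            if cy5 not in self.samples or cy3 not in self.samples:
                raise DesignError("array references an unknown sample")
        self.check_connected()

    def check_connected(self) -> None:
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[a[1]] for a in self.arrays]
        cols = [idx[a[2]] for a in self.arrays]
        n = len(self.samples)
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        if n_comp > 1:
            comps = [
                [s for s, i in idx.items() if labels[i] == c] for c in range(n_comp)
            ]
            raise DesignError(f"design graph is disconnected: components {comps}")

    def design_matrix(self) -> np.ndarray:
        """Arrays x samples incidence matrix: +1 at Cy5, -1 at Cy3."""
        idx = {s: i for i, s in enumerate(self.samples)}
        X = np.zeros((len(self.arrays), len(self.samples)))
        for r, (_aid, cy5, cy3) in enumerate(self.arrays):
            X[r, idx[cy5]] += 1.0
            X[r, idx[cy3]] -= 1.0
        return X


def build_experiment(
    design: pd.DataFrame,
    intensities: pd.DataFrame,
    replicate_summary: str = "mean",
) -> LoopDesignExperiment:
    """Assemble an experiment from design and intensity tables.

    ``design`` columns: array_id, cy5_sample, cy3_sample.  ``intensities``
    columns: array_id, probe_id, replicate, cy5, cy3.  Replicate log-ratios
    are combined by mean (default) or median.
    """
    if replicate_summary not in ("mean", "median"):
        raise ValueError("replicate_summary must be 'mean' or 'median'")
    if (intensities[["cy5", "cy3"]] <= 0).any().any():
        bad = intensities[(intensities["cy5"] <= 0) | (intensities["cy3"] <= 0)]
        raise ValueError(
            f"non-positive intensities for probes {sorted(bad['probe_id'].unique())[:5]}"
        )
    work = intensities.assign(m=np.log2(intensities["cy5"] / intensities["cy3"]))
    agg = getattr(work.groupby(["array_id", "probe_id"])["m"], replicate_summary)()
    M = agg.unstack("probe_id")
    samples = []
    for col in ("cy5_sample", "cy3_sample"):
        for s in design[col]:
            if s not in samples:
                samples.append(s)
    arrays = [
        (str(r.array_id), str(r.cy5_sample), str(r.cy3_sample))
        for r in design.itertuples()
    ]
    M = M.reindex(index=[a[0] for a in arrays])
    return LoopDesignExperiment(tuple(samples), arrays, M)


# ---------------------------------------------------------------------------
# Normalization and estimation
# ---------------------------------------------------------------------------

def median_normalize(m_values: np.ndarray) -> np.ndarray:
    """Subtract the per-array median from one array's M values."""
    m = np.asarray(m_values, dtype=float)
    if m.size == 0:
        raise ValueError("cannot normalize an empty array")
    if not np.all(np.isfinite(m)):
        bad = np.nonzero(~np.isfinite(m))[0]
        raise ValueError(f"non-finite M at positions {bad.tolist()[:5]}")
    return m - np.median(m)


def normalize_experiment(exp: LoopDesignExperiment) -> LoopDesignExperiment:
    """Apply global median normalization to every array."""
    M = exp.M.copy()
    for aid in M.index:
        row = M.loc[aid].to_numpy(dtype=float)
        if not np.all(np.isfinite(row)):
            bad = M.columns[~np.isfinite(row)].tolist()
            raise ValueError(f"non-finite M on array {aid} for probes {bad[:5]}")
        M.loc[aid] = median_normalize(row)
    return LoopDesignExperiment(exp.samples, list(exp.arrays), M)


@dataclass
class ExpressionMatrix:
    """Per-row (probe or transcript) per-sample log2 effects, sum-zero."""

    effects: pd.DataFrame  # rows x samples
    se: pd.DataFrame = field(default=None)  # same shape; NaN when dof = 0

    def __post_init__(self) -> None:
        sums = self.effects.sum(axis=1).to_numpy()
        if self.effects.shape[1] and np.any(np.abs(sums) > 1e-6):
            raise ValueError("per-row effects must sum to zero (identifiability)")
        if self.se is None:
            self.se = pd.DataFrame(
                np.nan, index=self.effects.index, columns=self.effects.columns
            )

    @property
    def samples(self) -> List[str]:
        return list(self.effects.columns)


def estimate_effects(exp: LoopDesignExperiment) -> ExpressionMatrix:
    """Least-squares per-sample effects from the loop design.

    Solves min ||M - X mu||^2 subject to sum(mu) = 0 for every probe at
    once.  Standard errors come from the residual variance (dof = arrays -
    (samples - 1)) and the diagonal of pinv(X'X); NaN when dof = 0.
    """
    exp.check_connected()
    X = exp.design_matrix()
    n_arrays, n_samples = X.shape
    if n_arrays < n_samples - 1:
        raise DesignError(
            f"underdetermined design: {n_arrays} arrays < {n_samples - 1} contrasts"
        )
    M = exp.M.to_numpy(dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("M contains non-finite values; normalize/inspect first")
    pinv = np.linalg.pinv(X)
    mu = pinv @ M  # samples x probes; min-norm => orthogonal to null space (1)
    dof = n_arrays - (n_samples - 1)
    se = np.full_like(mu, np.nan)
    if dof > 0:
        resid = M - X @ mu
        sigma2 = (resid ** 2).sum(axis=0) / dof
        unit = np.diag(np.linalg.pinv(X.T @ X))
        se = np.sqrt(np.outer(unit, sigma2))
    effects = pd.DataFrame(mu.T, index=exp.M.columns, columns=list(exp.samples))
    se_df = pd.DataFrame(se.T, index=exp.M.columns, columns=list(exp.samples))
    return ExpressionMatrix(effects, se_df)


def aggregate_probes(
    mat: ExpressionMatrix, probe_groups: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Average probe-level effects into transcript-level effects.

    Probes of one transcript are equally weighted; standard errors combine
    as the SE of a mean of independent estimates.
    """
    rows, ses, index = [], [], []
    for tid in sorted(probe_groups):
        probes = [p for p in probe_groups[tid] if p in mat.effects.index]
        if not probes:
            continue
        sub = mat.effects.loc[probes]
        rows.append(sub.mean(axis=0))
        sub_se = mat.se.loc[probes]
        ses.append(np.sqrt((sub_se ** 2).sum(axis=0)) / len(probes))
        index.append(tid)
    effects = pd.DataFrame(rows, index=index)
    se = pd.DataFrame(ses, index=index)
    return ExpressionMatrix(effects, se)


# ---------------------------------------------------------------------------
# Relative-expression tables and calls
# ---------------------------------------------------------------------------

def relative_expression_tables(
    mat: ExpressionMatrix, reference_sample: str
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """The two display tables of a reference-anchored expression figure.

    Table 1 (one column): each transcript's effect in the reference sample
    relative to the mean over transcripts in that sample.  Table 2: each
    transcript's effect per sample relative to its own reference-sample
    effect (reference column identically zero).
    """
    if reference_sample not in mat.effects.columns:
        raise ValueError(f"unknown reference sample {reference_sample!r}")
    ref = mat.effects[reference_sample]
    table1 = (ref - ref.mean()).to_frame(name=f"{reference_sample}_vs_mean")
    table2 = mat.effects.sub(ref, axis=0)
    return table1, table2


@dataclass
class CallTable:
    table: pd.DataFrame  # columns: max_delta, distinct, specificity
    tau_fold: float
    margin: float


def call_distinct(mat: ExpressionMatrix, tau_fold: float = 1.0) -> pd.DataFrame:
    """Flag transcripts with max pairwise |Delta mu| strictly above tau_fold."""
    if mat.effects.shape[1] < 2:
        raise ValueError("distinct calls need at least two samples")
    max_delta = mat.effects.max(axis=1) - mat.effects.min(axis=1)
    return pd.DataFrame({
        "max_delta": max_delta,
        "distinct": max_delta > tau_fold,
    })


def call_specificity(
    mat: ExpressionMatrix, focal_sample: str, margin: float = 1.0
) -> pd.Series:
    """Label transcripts predominant/depleted/none for one focal sample."""
    if focal_sample not in mat.effects.columns:
        raise ValueError(f"unknown focal sample {focal_sample!r}")
    focal = mat.effects[focal_sample]
    others = mat.effects.drop(columns=[focal_sample])
    labels = pd.Series("none", index=mat.effects.index, name=f"{focal_sample}_call")
    labels[focal - others.max(axis=1) >= margin] = "predominant"
    labels[others.min(axis=1) - focal >= margin] = "depleted"
    return labels


def make_call_table(
    mat: ExpressionMatrix,
    focal_sample: Optional[str] = None,
    tau_fold: float = 1.0,
    margin: float = 1.0,
) -> CallTable:
    table = call_distinct(mat, tau_fold)
    if focal_sample is not None:
        table["specificity"] = call_specificity(mat, focal_sample, margin)
    return CallTable(table, tau_fold, margin)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: List[str]
    newick: str


def correlation_distance_matrix(effects: pd.DataFrame) -> np.ndarray:
    """Full 1 - Pearson distance matrix between transcript rows."""
    values = effects.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = effects.index[sd == 0].tolist()
        raise ValueError(f"zero-variance rows (undefined correlation): {bad[:10]}")
    d = 1.0 - np.corrcoef(values)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _to_newick(node: hierarchy.ClusterNode, labels: List[str], parent_height: float) -> str:
    length = max(parent_height - node.dist, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def hierarchical_cluster(mat: ExpressionMatrix) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson correlation distance.

    Rows are pre-sorted by transcript id so ties break deterministically and
    the leaf *set* is invariant under input row permutation.
    """
    effects = mat.effects.sort_index()
    if len(effects) < 2:
        raise ValueError("clustering needs at least two transcripts")
    dist = correlation_distance_matrix(effects)
    condensed = dist[np.triu_indices(len(effects), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    labels = list(effects.index)
    leaves = hierarchy.leaves_list(Z)
    tree = hierarchy.to_tree(Z)
    newick = "(" + ",".join(
        _to_newick(child, labels, tree.dist) for child in (tree.left, tree.right)
    ) + ");" if not tree.is_leaf() else f"{labels[0]};"
    return ClusterResult(Z, [labels[i] for i in leaves], newick)
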