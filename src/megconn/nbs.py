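"""Network-based statistic (NBS) with covariate GLMs and permutation FWER control.

The NBS tests whether any connected subnetwork of edges shows an effect of a
predictor (a group contrast or a continuous association), controlling the
family-wise error rate at the network level:

1. wPLI values at each unique edge are z-scored across participants.
2. An ordinary-least-squares GLM (intercept + predictor + covariates) is fit
   at every edge; the predictor's t statistic forms an edge-wise map.
3. A primary threshold is fixed as the (1 − f) quantile of the observed
   direction-signed t values, chosen so that a fraction f (default 1%) of the
   unique edges is supra-threshold (40 of 4005 edges for 90 regions).
4. Connected components of the supra-threshold graph are the candidate
   networks; the test statistic is a component's extent (edge count).
5. The predictor is permuted (group labels directly, or Freedman–Lane
   residual permutation under the reduced model when covariates are present
   or the predictor is continuous); the SAME numeric threshold is re-applied
   in every permutation and the maximum component extent recorded, giving the
   null distribution.  Each observed component receives
   p_corr = (1 + #{null ≥ extent}) / (1 + n_permutations).

`NetworkBasedStatistic` is the model object (built from connectivity matrices
plus a cohort table); `fit()` returns an `NBSResults` carrying the edge
statistics, components, null distribution and a `summary()` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "DesignSpec",
    "EdgeStats",
    "ComponentResult",
    "NBSResults",
    "NetworkBasedStatistic",
    "ZScoredEdges",
    "zscore_edges",
    "edge_glm",
    "select_threshold",
    "extract_components",
    "nbs_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignSpec:
    """One NBS analysis: predictor of interest, covariates, direction.

    ``mode`` is ``"group_contrast"`` (binary group regressor, equivalent to a
    covariate-adjusted two-sample t-test) or ``"association"`` (continuous
    predictor regression).  ``direction`` selects the tested tail: "positive"
    tests predictor-increases-connectivity, "negative" the reverse; the two
    one-sided analyses are run separately.  ``contrast_level`` names the group
    coded 1 in group_contrast mode (default: last of the sorted levels).
    """

    mode: str
    predictor: str
    covariates: tuple[str, ...] = ("age_at_scan", "sex")
    direction: str = "positive"
    target_edge_fraction: float = 0.01
    n_permutations: int = 5000
    alpha: float = 0.05
    contrast_level: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("group_contrast", "association"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} also listed as covariate")
        if not 0.0 < self.target_edge_fraction < 1.0:
            raise ValueError("target_edge_fraction must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "positive" else -1.0


@dataclass
class EdgeStats:
    """Edge-wise GLM t statistics for the predictor of interest."""

    t_values: np.ndarray  # (n_regions, n_regions) symmetric, diag 0
    df: int
    threshold: float  # primary threshold in (direction-signed) t units


@dataclass
class ComponentResult:
    """One connected supra-threshold subnetwork."""

    edges: frozenset[tuple[int, int]]
    nodes: frozenset[int]
    extent: int
    p_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.extent != len(self.edges):
            raise ValueError("extent must equal |edges|")


@dataclass
class ZScoredEdges:
    """Stack of per-subject edge vectors, z-scored across participants.

    ``values`` is (n_subjects, n_edges) over the unique (upper-triangle)
    edges indexed by ``edge_i``/``edge_j``.  Zero-variance edges are set to
    all-zero and flagged in ``zero_variance``.
    """

    values: np.ndarray
    subject_ids: list[str]
    n_regions: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    zero_variance: np.ndarray
    band_name: str | None = None

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def zscore_edges(stack) -> ZScoredEdges:
    """Z-score each unique edge across participants (sample SD, ddof=1).

    ``stack`` is a list of :class:`ConnectivityMatrix` sharing band and shape,
    or an (n_subjects, R, R) array.
    """
    if isinstance(stack, np.ndarray):
        mats = np.asarray(stack, dtype=float)
        subject_ids = [f"S{idx:03d}" for idx in range(mats.shape[0])]
        band_name = None
    else:
        stack = list(stack)
        if len(stack) == 0:
            raise ValueError("empty stack")
        ref = stack[0]
        for m in stack[1:]:
            if not isinstance(m, ConnectivityMatrix):
                raise TypeError("stack items must be ConnectivityMatrix")
            if m.values.shape != ref.values.shape:
                raise ValueError("connectivity matrices differ in shape")
            if m.band.name != ref.band.name:
                raise ValueError(
                    f"band mismatch: {m.band.name!r} vs {ref.band.name!r}"
                )
        mats = np.stack([m.values for m in stack])
        subject_ids = [m.subject_id for m in stack]
        band_name = ref.band.name
    if mats.shape[0] < 3:
        raise ValueError("need at least 3 subjects to z-score edges")
    R = mats.shape[1]
    iu, ju = np.triu_indices(R, k=1)
    vals = mats[:, iu, ju]  # (n, E)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    z = (vals - mean) / sd_safe
    z[:, zero_var] = 0.0
    if zero_var.any():
        logger.info("zscore_edges: %d zero-variance edges flagged", int(zero_var.sum()))
    return ZScoredEdges(
        values=z,
        subject_ids=subject_ids,
        n_regions=R,
        edge_i=iu,
        edge_j=ju,
        zero_variance=zero_var,
        band_name=band_name,
    )


def _encode_design(
    cohort: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], int, np.ndarray]:
    """Build the design matrix [intercept, predictor, covariates...].

    Returns (X, column_names, predictor_column_index, kept_row_mask); rows
    with missing values in any used column are dropped (listwise deletion).
    """
    used = [design.predictor, *design.covariates]
    for col in used:
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} missing from cohort table")
    sub = cohort[used]
    kept = ~sub.isna().any(axis=1)
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, len(cohort))
    sub = sub[kept]

    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    pred = sub[design.predictor]
    if design.mode == "group_contrast":
        levels = sorted(pred.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"group_contrast predictor {design.predictor!r} must have exactly "
                f"2 levels, got {levels}"
            )
        coded = design.contrast_level if design.contrast_level is not None else levels[-1]
        if coded not in levels:
            raise ValueError(f"contrast_level {coded!r} not among group levels {levels}")
        cols.append((pred.astype(str) == coded).to_numpy(dtype=float))
        names.append(f"{design.predictor}[{coded}]")
    else:
        cols.append(pred.to_numpy(dtype=float))
        names.append(design.predictor)
    pred_idx = 1
    for cov in design.covariates:
        col = sub[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # drop first level as reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix; check for collinear columns among {names}"
        )
    return X, names, pred_idx, kept.to_numpy()


def _glm_t(X: np.ndarray, Y: np.ndarray, pred_idx: int, xtx_inv: np.ndarray | None = None):
    """Vectorised OLS t statistics for one coefficient across many responses.

    X is (n, p), Y is (n, E); returns (t (E,), df).
    """
    n, p = X.shape
    if xtx_inv is None:
        xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # (p, E)
    resid = Y - X @ beta
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[pred_idx, pred_idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[pred_idx] / np.where(se > 0, se, 1.0), 0.0)
    return t, df


def edge_glm(
    z_stack: ZScoredEdges, cohort: pd.DataFrame, design: DesignSpec
) -> EdgeStats:
    """Edge-wise OLS of z-scored wPLI on [intercept, predictor, covariates].

    The returned t matrix is unsigned by direction (raw predictor t); the
    direction is applied downstream as a sign filter.
    """
    X, _, pred_idx, kept = _encode_design(cohort, design)
    Y = z_stack.values[kept]
    t_flat, df = _glm_t(X, Y, pred_idx)
    R = z_stack.n_regions
    T = np.zeros((R, R))
    T[z_stack.edge_i, z_stack.edge_j] = t_flat
    T = T + T.T
    return EdgeStats(t_values=T, df=df, threshold=np.nan)


def select_threshold(t_signed: np.ndarray, target_edge_fraction: float) -> float:
    """Primary threshold: (1 − f) quantile of direction-signed edge t values.

    Returns the t value such that round(f × n_edges) edges (at least one) are
    supra-threshold (t ≥ threshold); with ties at the cut all tied edges are
    kept, so the supra count may exceed the target (logged).
    """
    t = np.asarray(t_signed, dtype=float).ravel()
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite edge statistics")
    k = int(round(target_edge_fraction * t.size))
    if k < 1:
        warnings.warn(
            f"fewer unique edges ({t.size}) than 1/target_edge_fraction; "
            "keeping one edge",
            stacklevel=2,
        )
        k = 1
    thr = float(np.sort(t)[::-1][k - 1])
    n_supra = int((t >= thr).sum())
    if n_supra > k:
        logger.info(
            "threshold ties: %d edges at/above cut (target %d)", n_supra, k
        )
    return thr


def extract_components(supra_edges) -> list[ComponentResult]:
    """Connected components of the undirected supra-threshold edge graph.

    Components are sorted by extent (edge count) descending, ties by smallest
    node index; p_corrected is left unset.
    """
    edges = [(int(i), int(j)) for i, j in supra_edges]
    if not edges:
        return []
    G = nx.Graph()
    G.add_edges_from(edges)
    comps = []
    for nodes in nx.connected_components(G):
        sub = G.subgraph(nodes)
        comp_edges = frozenset(tuple(sorted(e)) for e in sub.edges())
        comps.append(
            ComponentResult(
                edges=comp_edges,
                nodes=frozenset(int(n) for n in nodes),
                extent=sub.number_of_edges(),
            )
        )
    comps.sort(key=lambda c: (-c.extent, min(c.nodes)))
    return comps


def _max_extent(ei: np.ndarray, ej: np.ndarray) -> int:
    """Max connected-component edge count via union-find (permutation loop)."""
    if ei.size == 0:
        return 0
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    edge_count: dict[int, int] = {}
    for a, b in zip(ei.tolist(), ej.tolist()):
        if a not in parent:
            parent[a] = a
            edge_count[a] = 0
        if b not in parent:
            parent[b] = b
            edge_count[b] = 0
        ra, rb = find(a), find(b)
        if ra == rb:
            edge_count[ra] += 1
        else:
            parent[rb] = ra
            edge_count[ra] += edge_count.pop(rb) + 1
    return max(edge_count[find(r)] for r in edge_count)


@dataclass
class NBSResults:
    """Results of one NBS analysis.

    ``components`` are sorted by extent descending and each carries
    p_corrected = (1 + #{null_max ≥ extent}) / (1 + n_permutations_used).
    """

    design: DesignSpec
    edge_stats: EdgeStats
    components: list[ComponentResult]
    null_max_extents: np.ndarray
    n_permutations_used: int
    exhaustive: bool
    seed: int | None
    n_subjects_used: int
    n_dropped: int
    band_name: str | None = None
    zero_variance_edges: int = 0
    edge_i: np.ndarray | None = None
    edge_j: np.ndarray | None = None

    @property
    def threshold(self) -> float:
        return self.edge_stats.threshold

    def significant_components(self, alpha: float | None = None) -> list[ComponentResult]:
        a = self.design.alpha if alpha is None else alpha
        return [c for c in self.components if c.p_corrected is not None and c.p_corrected <= a]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": k,
                "extent": c.extent,
                "n_nodes": len(c.nodes),
                "p_corrected": c.p_corrected,
                "significant": c.p_corrected <= self.design.alpha,
            }
            for k, c in enumerate(self.components)
        ]
        return pd.DataFrame(
            rows, columns=["component", "extent", "n_nodes", "p_corrected", "significant"]
        )

    def summary(self, max_components: int = 10) -> str:
        d = self.design
        lines = [
            "Network-based statistic",
            "=" * 60,
            f"mode:            {d.mode}",
            f"predictor:       {d.predictor} ({d.direction} direction)",
            f"covariates:      {', '.join(d.covariates) if d.covariates else '(none)'}",
            f"band:            {self.band_name or '(unspecified)'}",
            f"subjects used:   {self.n_subjects_used} ({self.n_dropped} dropped, listwise)",
            f"GLM df:          {self.edge_stats.df}",
            f"primary t thresh: {self.edge_stats.threshold:.4f} "
            f"(target fraction {d.target_edge_fraction})",
            f"permutations:    {self.n_permutations_used}"
            + (" (exhaustive)" if self.exhaustive else ""),
            "-" * 60,
        ]
        if not self.components:
            lines.append("no supra-threshold components")
        else:
            df = self.to_frame().head(max_components)
            lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def plot_network(self, component: int = 0, ax=None):
        """Adjacency spy plot of one component over the full region grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        R = self.edge_stats.t_values.shape[0]
        A = np.zeros((R, R))
        comp = self.components[component]
        for i, j in comp.edges:
            A[i, j] = A[j, i] = 1.0
        ax.imshow(A, cmap="Greys", interpolation="nearest")
        ax.set_xlabel("region")
        ax.set_ylabel("region")
        ax.set_title(
            f"component {component}: {comp.extent} edges, {len(comp.nodes)} nodes, "
            f"p_corr={comp.p_corrected:.4g}"
        )
        return ax


class NetworkBasedStatistic:
    """NBS model: connectivity stack + cohort table + design.

    Parameters
    ----------
    z_stack : ZScoredEdges
        Per-subject z-scored edge vectors (see :func:`zscore_edges`).
    cohort : DataFrame
        One row per subject, aligned with the stack rows; must contain the
        predictor and covariate columns.
    design : DesignSpec
    """

    def __init__(self, z_stack: ZScoredEdges, cohort: pd.DataFrame, design: DesignSpec):
        if len(cohort) != z_stack.n_subjects:
            raise ValueError(
                f"cohort has {len(cohort)} rows but stack has "
                f"{z_stack.n_subjects} subjects"
            )
        if z_stack.n_subjects < 6:
            raise ValueError("need at least 6 subjects for permutation inference")
        self.z_stack = z_stack
        self.cohort = cohort.reset_index(drop=True)
        self.design = design

    @classmethod
    def from_matrices(cls, matrices, cohort: pd.DataFrame, design: DesignSpec):
        """Build from a list of per-subject ConnectivityMatrix (one band)."""
        return cls(zscore_edges(matrices), cohort, design)

    def fit(
        self, n_permutations: int | None = None, seed: int | None = None
    ) -> NBSResults:
        """Run the observed pipeline and the permutation null; return results."""
        design = self.design
        nperm = design.n_permutations if n_permutations is None else n_permutations
        rng_seed = design.seed if seed is None else seed
        rng = np.random.default_rng(rng_seed)

        X, names, pred_idx, kept = _encode_design(self.cohort, design)
        Y = self.z_stack.values[kept]
        n = X.shape[0]
        if n < 6:
            raise ValueError("fewer than 6 subjects after listwise deletion")
        xtx_inv = np.linalg.inv(X.T @ X)
        t_flat, df = _glm_t(X, Y, pred_idx, xtx_inv)
        signed = design.sign * t_flat
        thr = select_threshold(signed, design.target_edge_fraction)
        supra = signed >= thr
        ei, ej = self.z_stack.edge_i[supra], self.z_stack.edge_j[supra]
        components = extract_components(zip(ei, ej))

        use_fl = design.mode == "association" or len(design.covariates) > 0
        exhaustive = False
        if design.mode == "group_contrast" and not use_fl:
            g = X[:, pred_idx].astype(int)
            n1 = int(g.sum())
            n_distinct = comb(n, n1)
            exhaustive = n_distinct <= nperm

        null_max = []
        if exhaustive:
            observed = frozenset(np.flatnonzero(X[:, pred_idx] > 0).tolist())
            for ones in combinations(range(n), n1):
                if frozenset(ones) == observed:
                    continue
                Xp = X.copy()
                Xp[:, pred_idx] = 0.0
                Xp[list(ones), pred_idx] = 1.0
                null_max.append(self._perm_extent(Xp, Y, pred_idx, design.sign, thr))
            nperm_used = n_distinct - 1
        elif use_fl:
            # Freedman-Lane: permute residuals of the reduced model
            X0 = np.delete(X, pred_idx, axis=1)
            beta0 = np.linalg.lstsq(X0, Y, rcond=None)[0]
            fitted0 = X0 @ beta0
            resid0 = Y - fitted0
            for _ in range(nperm):
                perm = rng.permutation(n)
                Ystar = fitted0 + resid0[perm]
                null_max.append(self._perm_extent(X, Ystar, pred_idx, design.sign, thr))
            nperm_used = nperm
        else:
            for _ in range(nperm):
                Xp = X.copy()
                Xp[:, pred_idx] = X[rng.permutation(n), pred_idx]
                null_max.append(self._perm_extent(Xp, Y, pred_idx, design.sign, thr))
            nperm_used = nperm
        null_max = np.asarray(null_max, dtype=int)

        out_components = []
        for c in components:
            p = (1 + int((null_max >= c.extent).sum())) / (1 + nperm_used)
            out_components.append(
                ComponentResult(edges=c.edges, nodes=c.nodes, extent=c.extent, p_corrected=p)
            )

        R = self.z_stack.n_regions
        T = np.zeros((R, R))
        T[self.z_stack.edge_i, self.z_stack.edge_j] = t_flat
        edge_stats = EdgeStats(t_values=T + T.T, df=df, threshold=thr)
        return NBSResults(
            design=design,
            edge_stats=edge_stats,
            components=out_components,
            null_max_extents=null_max,
            n_permutations_used=nperm_used,
            exhaustive=exhaustive,
            seed=rng_seed,
            n_subjects_used=n,
            n_dropped=int((~kept).sum()),
            band_name=self.z_stack.band_name,
            zero_variance_edges=int(self.z_stack.zero_variance.sum()),
            edge_i=self.z_stack.edge_i,
            edge_j=self.z_stack.edge_j,
        )

    def _perm_extent(self, X, Y, pred_idx, sign, thr) -> int:
        t, _ = _glm_t(X, Y, pred_idx)
        supra = sign * t >= thr
        return _max_extent(self.z_stack.edge_i[supra], self.z_stack.edge_j[supra])


def nbs_test(
    z_stack: ZScoredEdges,
    cohort: pd.DataFrame,
    design: DesignSpec,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> NBSResults:
    """Functional wrapper: build the model and fit in one call."""
    return NetworkBasedStatistic(z_stack, cohort, design).fit(
        n_permutations=n_permutations, seed=seed
    )
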