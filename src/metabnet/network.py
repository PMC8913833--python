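"""Metabolic network construction.

Nodes are metabolites; an edge is a statistical association between two
metabolites' concentrations across subjects, measured as the absolute
Spearman rank correlation at one (group, time point).  Matrices are
binarized over a sweep of correlation thresholds, and the connections
consistently present over time are extracted into a backbone network with
a one-tailed sign test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .panel import MetabolitePanel

#: The analysis threshold sweep: 0.41 to 0.49 at a 0.01 interval.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(0.41, 0.495, 0.01), 2)
)

#: Significance level of the one-tailed backbone sign test.
DEFAULT_SIGN_ALPHA = 0.025


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of absolute Spearman correlations, zero diagonal.

    ``time_point`` is a 1-based index, or the string ``"backbone"`` for the
    time-aggregated consistent-connection matrix.
    """

    values: np.ndarray
    panel: MetabolitePanel
    group: str
    time_point: int | str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        m = len(self.panel)
        if v.shape != (m, m):
            raise InvalidParameterError(
                f"matrix shape {v.shape} does not match panel size {m}"
            )
        if not np.allclose(v, v.T):
            raise InvalidParameterError("correlation matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InvalidParameterError("correlation matrix diagonal must be 0")
        if np.any(v < 0) or np.any(v > 1):
            raise InvalidParameterError("entries must be absolute correlations in [0, 1]")


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted metabolic network at one threshold."""

    adjacency: np.ndarray
    panel: MetabolitePanel
    threshold: float | None
    provenance: tuple

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        object.__setattr__(self, "adjacency", a)
        m = len(self.panel)
        if a.shape != (m, m):
            raise InvalidParameterError("adjacency shape does not match panel")
        if not np.array_equal(a, a.T):
            raise InvalidParameterError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise InvalidParameterError("adjacency must have no self-loops")

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edges(self) -> list[tuple[str, str]]:
        names = self.panel.names
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(names[a], names[b]) for a, b in zip(i, j)]


@dataclass(frozen=True)
class BackboneResult:
    """Consistent-connection (backbone) matrix and its sign-test evidence."""

    matrix: CorrelationMatrix
    sign_test_p: np.ndarray
    alpha: float
    eligible: np.ndarray
    n_time_points: int
    aggregate: str


def _subject_matrix(table: pd.DataFrame, panel: MetabolitePanel,
                    group: str | None, time_point: int) -> np.ndarray:
    """Subjects x metabolites concentration array for one (group, time point)."""
    sub = table[table["time_point"] == time_point]
    if group is not None:
        sub = sub[sub["group"] == group]
    if sub.empty:
        raise InsufficientDataError(
            f"no records for group={group!r} time_point={time_point}"
        )
    wide = sub.pivot_table(index="subject", columns="metabolite",
                           values="concentration", aggfunc="first")
    missing = [m for m in panel if m not in wide.columns]
    if missing:
        raise InsufficientDataError(f"metabolites absent at time point {time_point}: {missing}")
    wide = wide.reindex(columns=list(panel.names)).sort_index()
    if wide.isna().any().any():
        raise InsufficientDataError(
            f"incomplete records for group={group!r} time_point={time_point}"
        )
    if len(wide) < 3:
        raise InsufficientDataError(
            f"need >= 3 subjects at (group={group!r}, time_point={time_point}), "
            f"got {len(wide)}"
        )
    return wide.to_numpy(dtype=float)


def abs_spearman_from_array(data: np.ndarray) -> np.ndarray:
    """|Spearman| matrix from a subjects x metabolites array.

    Pearson correlation of mid-ranks, which is exactly Spearman's rho with
    average-rank tie handling; undefined (zero-variance) entries become 0.
    """
    ranks = stats.rankdata(data, axis=0, method="average")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(np.nan_to_num(np.asarray(rho, dtype=float), nan=0.0))
    vals = np.abs(rho)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return np.clip(vals, 0.0, 1.0)


def _backbone_core(stack: np.ndarray, alpha: float, aggregate: str,
                   count_mode: str, count_threshold: float):
    """Sign-test eligibility and time-aggregated values from a (T, M, M)
    stack of |rho| matrices."""
    n_t = stack.shape[0]
    if count_mode == "raw":
        k = (stack > 0).sum(axis=0)
    else:
        k = (stack > count_threshold).sum(axis=0)
    # one-tailed sign test: P(X >= k), X ~ Bin(T, 1/2)
    pvals = stats.binom.sf(k - 1, n_t, 0.5)
    eligible = pvals < alpha
    agg = stack.min(axis=0) if aggregate == "min" else np.median(stack, axis=0)
    values = np.where(eligible, agg, 0.0)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(eligible, False)
    return values, pvals, eligible


def spearman_matrix(table: pd.DataFrame, group: str | None, time_point: int,
                    panel: MetabolitePanel | None = None) -> CorrelationMatrix:
    """Absolute Spearman correlation matrix across subjects.

    Average-rank (mid-rank) tie handling; a zero-variance metabolite yields
    undefined correlations, which are set to 0 with a warning.
    """
    if panel is None:
        panel = MetabolitePanel(tuple(pd.unique(table["metabolite"])))
    data = _subject_matrix(table, panel, group, time_point)
    if np.any(np.ptp(data, axis=0) == 0):
        warnings.warn(
            "zero-variance metabolite: undefined correlations set to 0",
            RuntimeWarning, stacklevel=2,
        )
    vals = abs_spearman_from_array(data)
    return CorrelationMatrix(values=vals, panel=panel,
                             group=group if group is not None else "all",
                             time_point=time_point)


def binarize(matrix: CorrelationMatrix, threshold: float) -> BinaryNetwork:
    """Edge wherever |rho| is strictly above the threshold."""
    if not 0.0 <= threshold < 1.0:
        raise InvalidParameterError(f"threshold must be in [0, 1), got {threshold}")
    adj = matrix.values > threshold
    return BinaryNetwork(adjacency=adj, panel=matrix.panel, threshold=threshold,
                         provenance=(matrix.group, matrix.time_point))


def threshold_sweep(matrix: CorrelationMatrix,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                    ) -> list[BinaryNetwork]:
    """Binarize at each threshold of a strictly increasing sweep."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidParameterError("threshold list must be non-empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidParameterError("thresholds must be strictly increasing")
    return [binarize(matrix, t) for t in thresholds]


def backbone(matrices: Sequence[CorrelationMatrix],
             alpha: float = DEFAULT_SIGN_ALPHA,
             aggregate: str = "min",
             count_mode: str = "raw",
             count_threshold: float = 0.41) -> BackboneResult:
    """Extract the consistent-connection (backbone) matrix over time.

    For each metabolite pair the one-tailed sign test counts the time points
    supporting a connection (|rho| > 0 in ``raw`` mode, |rho| above the
    analysis threshold in ``strict`` mode) against the null of no connection:
    p = P(Bin(T, 1/2) >= k).  Pairs with p < alpha keep the minimum (or
    median) |rho| over time; all others are set to 0.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise InvalidParameterError("backbone needs >= 2 time points")
    panel = matrices[0].panel
    group = matrices[0].group
    for mat in matrices[1:]:
        if mat.panel.names != panel.names or mat.group != group:
            raise InvalidParameterError("backbone inputs must share panel and group")
    if aggregate not in ("min", "median"):
        raise InvalidParameterError(f"unknown aggregate {aggregate!r}")
    if count_mode not in ("raw", "strict"):
        raise InvalidParameterError(f"unknown count_mode {count_mode!r}")
    stack = np.stack([m.values for m in matrices])  # (T, M, M)
    values, pvals, eligible = _backbone_core(stack, alpha, aggregate,
                                             count_mode, count_threshold)
    mat = CorrelationMatrix(values=values, panel=panel, group=group,
                            time_point="backbone")
    return BackboneResult(matrix=mat, sign_test_p=pvals, alpha=alpha,
                          eligible=eligible, n_time_points=stack.shape[0],
                          aggregate=aggregate)


# ---------------------------------------------------------------------------
# serialization

def write_matrix_csv(matrix: CorrelationMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.panel.names,
                      columns=matrix.panel.names)
    df.to_csv(path)


def read_matrix_csv(path, group: str = "all",
                    time_point: int | str = 1) -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    panel = MetabolitePanel(tuple(df.columns))
    return CorrelationMatrix(values=df.to_numpy(dtype=float), panel=panel,
                             group=group, time_point=time_point)


def write_edge_list(net: BinaryNetwork, path, weights: CorrelationMatrix | None = None) -> None:
    """TSV edge list ``metabolite_a<TAB>metabolite_b<TAB>weight`` (connectogram
    input).  A leading comment line records the full node set so isolated
    nodes survive a round trip."""
    lines = ["# nodes: " + ",".join(net.panel.names)]
    for a, b in net.edges():
        if weights is not None:
            w = weights.values[net.panel.index(a), net.panel.index(b)]
        else:
            w = 1.0
        lines.append(f"{a}\t{b}\t{w:.6g}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edge_list(path, threshold: float | None = None,
                   provenance: tuple = ("file", "edges")) -> BinaryNetwork:
    nodes: list[str] = []
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# nodes:"):
                    nodes = [n for n in line.split(":", 1)[1].strip().split(",") if n]
                continue
            a, b = line.split("\t")[:2]
            pairs.append((a, b))
    if not nodes:
        seen: dict[str, None] = {}
        for a, b in pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        nodes = list(seen)
    panel = MetabolitePanel(tuple(nodes))
    m = len(panel)
    adj = np.zeros((m, m), dtype=bool)
    for a, b in pairs:
        i, j = panel.index(a), panel.index(b)
        adj[i, j] = adj[j, i] = True
    return BinaryNetwork(adjacency=adj, panel=panel, threshold=threshold,
                         provenance=provenance)
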