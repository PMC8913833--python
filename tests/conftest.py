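import numpy as np
import pandas as pd
import pytest

from metabnet.network import BinaryNetwork
from metabnet.panel import MetabolitePanel


@pytest.fixture(scope="session")
def small_panel():
    return MetabolitePanel(("A", "B", "C", "D", "E"))


def make_table(data: dict[str, list[float]], group: str = "g",
               time_point: int = 1, crlb: float = 5.0) -> pd.DataFrame:
    """Tidy table from {metabolite: concentrations-per-subject}."""
    records = []
    n = len(next(iter(data.values())))
    for metab, vals in data.items():
        assert len(vals) == n
        for i, v in enumerate(vals):
            records.append((group, f"{group}-{i + 1:02d}", time_point, metab,
                            float(v), crlb))
    return pd.DataFrame.from_records(
        records, columns=["group", "subject", "time_point", "metabolite",
                          "concentration", "crlb"])


def net_from_edges(n_nodes: int, edges, threshold=None) -> BinaryNetwork:
    panel = MetabolitePanel(tuple(f"m{i}" for i in range(n_nodes)))
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryNetwork(adjacency=adj, panel=panel, threshold=threshold,
                         provenance=("test", 0))


def random_net(n_nodes: int, n_edges: int, rng) -> BinaryNetwork:
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    return net_from_edges(n_nodes, [pairs[k] for k in idx])


def floyd_warshall_hops(adj: np.ndarray) -> np.ndarray:
    """Independent all-pairs shortest-hop oracle (triple loop)."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_eff(adj: np.ndarray) -> float:
    d = floyd_warshall_hops(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def brute_local_eff(adj: np.ndarray) -> np.ndarray:
    """Induced-neighbourhood-subgraph oracle for per-node local efficiency."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = brute_global_eff(sub)
    return out
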