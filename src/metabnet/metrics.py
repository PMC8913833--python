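"""Efficiency-based small-world statistics of binary metabolic networks.

Global efficiency (mean inverse shortest-path length, Latora-Marchiori) and
per-node local efficiency are compared against an ensemble of degree-matched
random networks produced by Maslov-Sneppen double-edge swaps:

    gamma = E_global(real) / mean E_global(random)
    lambda = mean E_local(real) / mean E_local(random)
    sigma  = lambda / gamma            (small-world if sigma > 1)

A network is scored small-world when sigma > 1; gamma and lambda are
reported but not gated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _engine
from .errors import InvalidParameterError, UndefinedRatioError
from .network import BinaryNetwork

DEFAULT_N_RANDOM = 1000
DEFAULT_N_SWAP_PER_EDGE = 10


@dataclass(frozen=True)
class EfficiencyResult:
    e_global: float
    e_local: dict[str, float]

    @property
    def e_local_mean(self) -> float:
        return float(np.mean(list(self.e_local.values())))


@dataclass(frozen=True)
class SmallWorldResult:
    real: EfficiencyResult
    rand_e_global_mean: float
    rand_e_local_mean: float
    gamma: float
    lam: float
    sigma: float
    n_random: int
    meets_criterion: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "e_global": self.real.e_global,
            "e_local": dict(self.real.e_local),
            "rand_e_global_mean": self.rand_e_global_mean,
            "rand_e_local_mean": self.rand_e_local_mean,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "n_random": self.n_random,
            "meets_criterion": self.meets_criterion,
            "seed": self.seed,
        }


def _adj(net: BinaryNetwork) -> np.ndarray:
    return net.adjacency.astype(np.uint8)


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs hop-count matrix; np.inf marks disconnected pairs."""
    return _engine.hop_matrix(_adj(net))


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d(i, j) over all node pairs, with 1/inf = 0."""
    if len(net.panel) < 2:
        raise InvalidParameterError("global efficiency needs >= 2 nodes")
    return float(_engine.global_eff(_adj(net)))


def local_efficiency(net: BinaryNetwork) -> dict[str, float]:
    """Per-node efficiency of the neighbourhood-induced subgraph."""
    if len(net.panel) < 2:
        raise InvalidParameterError("local efficiency needs >= 2 nodes")
    vals = _engine.local_eff(_adj(net))
    return {name: float(v) for name, v in zip(net.panel.names, vals)}


def efficiency(net: BinaryNetwork) -> EfficiencyResult:
    return EfficiencyResult(e_global=global_efficiency(net),
                            e_local=local_efficiency(net))


def rewire_preserving_degree(net: BinaryNetwork,
                             n_swap_per_edge: int = DEFAULT_N_SWAP_PER_EDGE,
                             seed: int = 0) -> BinaryNetwork:
    """One degree-preserving randomization (double-edge swaps).

    The degree sequence is preserved exactly; swaps that would introduce a
    self-loop or multi-edge are rejected and retried within a budget of
    100x the target swap count.  With fewer than 2 edges no legal swap
    exists and the input is returned unchanged with a warning.
    """
    if net.n_edges < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire", RuntimeWarning,
                      stacklevel=2)
        return net
    adj, swaps, target = _engine.rewire(_adj(net), int(n_swap_per_edge), int(seed))
    if swaps < target:
        warnings.warn(
            f"rewiring under-mixed: {swaps}/{target} swaps within budget",
            RuntimeWarning, stacklevel=2,
        )
    return BinaryNetwork(adjacency=adj.astype(bool), panel=net.panel,
                         threshold=net.threshold,
                         provenance=net.provenance + ("rewired",))


def small_worldness(net: BinaryNetwork,
                    n_random: int = DEFAULT_N_RANDOM,
                    n_swap_per_edge: int = DEFAULT_N_SWAP_PER_EDGE,
                    seed: int = 0) -> SmallWorldResult:
    """Compare a network's efficiencies with its degree-matched null ensemble.

    Raises :class:`UndefinedRatioError` if the ensemble's mean global or mean
    local efficiency is zero (the normalized ratios are then undefined).
    """
    if net.n_edges < 1:
        raise InvalidParameterError("small-worldness needs >= 1 edge")
    if n_random < 1:
        raise InvalidParameterError("n_random must be >= 1")
    real = efficiency(net)
    rand_eg, rand_el = _engine.ensemble_means(
        _adj(net), int(n_random), int(n_swap_per_edge), int(seed)
    )
    if rand_eg == 0.0 or rand_el == 0.0:
        raise UndefinedRatioError(
            f"degenerate null ensemble for {net.provenance} at threshold "
            f"{net.threshold}: mean E_global={rand_eg}, mean E_local={rand_el}"
        )
    gamma = real.e_global / rand_eg
    lam = real.e_local_mean / rand_el
    sigma = lam / gamma
    return SmallWorldResult(real=real, rand_e_global_mean=float(rand_eg),
                            rand_e_local_mean=float(rand_el), gamma=float(gamma),
                            lam=float(lam), sigma=float(sigma),
                            n_random=int(n_random),
                            meets_criterion=bool(sigma > 1.0), seed=int(seed))
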