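"""Degree-matched random networks and small-world normalization.

Real-network clustering and path length are normalized against an ensemble
of Maslov–Sneppen rewired surrogates that preserve the binary degree
sequence exactly. For weighted networks the topology is rewired as binary
and the original multiset of edge weights is then reassigned to the new
edges in random order, so the weight distribution is conserved while the
placement is randomized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._graphops import double_edge_swap
from .metrics import GlobalMetrics, clustering_coefficient, distance_matrix, path_length_harmonic
from .network import ThresholdedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "SmallWorldParams",
    "rewire_preserving_degree",
    "null_metric_distribution",
    "small_world_params",
]

_MAX_SEED = 2**31 - 1


@dataclass
class NullEnsemble:
    """Per-surrogate mean clustering and harmonic path length."""

    clustering_means: np.ndarray
    path_lengths: np.ndarray

    @property
    def size(self) -> int:
        return len(self.clustering_means)


@dataclass
class SmallWorldParams:
    """Normalized clustering (gamma), path length (lambda) and sigma = gamma/lambda."""

    gamma: float
    lam: float
    sigma: float


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) % _MAX_SEED


def _rewired_adjacency(
    w: np.ndarray,
    weighted: bool,
    swaps_per_edge: int,
    kernel_seed: int,
    perm_rng: np.random.Generator,
) -> np.ndarray:
    """Rewired dense adjacency (the hot path; skips dataclass wrapping)."""
    iu, ju = np.nonzero(np.triu(w, 1))
    m = iu.size
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    weights = w[iu, ju]
    adj = w > 0
    iu = iu.astype(np.int64)
    ju = ju.astype(np.int64)
    n_attempts = int(swaps_per_edge) * m
    nsucc = double_edge_swap(adj, iu, ju, n_attempts, int(kernel_seed))
    if nsucc < m // 10:
        logger.info(
            "rewiring achieved only %d/%d successful swaps (%d attempts)",
            nsucc, m, n_attempts,
        )
    if weighted:
        weights = perm_rng.permutation(weights)
    else:
        weights = np.ones(m)
    out = np.zeros_like(w)
    out[iu, ju] = weights
    out[ju, iu] = weights
    return out


def rewire_preserving_degree(
    net: ThresholdedNetwork, swaps_per_edge: int = 10, seed: int = 0
) -> ThresholdedNetwork:
    """Degree-preserving double-edge-swap rewiring of one network.

    Attempts ``swaps_per_edge * |E|`` swaps; proposals creating self-loops
    or multi-edges are rejected, so the binary degree sequence is preserved
    exactly. If very few swaps succeed (rigid graphs such as a triangle)
    the current state is returned and the success rate logged. Weighted
    networks are rewired as binary topology with the original weight
    multiset then reassigned to the new edges in random order.
    """
    kernel_seed, perm_seed = _child_seeds(seed, 2)
    out = _rewired_adjacency(
        net.adjacency, net.kind == "weighted", swaps_per_edge,
        int(kernel_seed), np.random.default_rng(int(perm_seed)),
    )
    return ThresholdedNetwork(
        adjacency=out, sparsity=net.sparsity, kind=net.kind,
        region_names=list(net.region_names),
    )


def null_metric_distribution(
    net: ThresholdedNetwork,
    m: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    clustering_variant: str = "onnela",
) -> NullEnsemble:
    """Mean clustering and harmonic path length over ``m`` rewired surrogates."""
    if m < 1:
        raise ValueError("ensemble size must be at least 1")
    seeds = _child_seeds(seed, m + 1)
    cs = np.empty(m)
    ls = np.empty(m)
    weighted = net.kind == "weighted"
    perm_rng = np.random.default_rng(int(seeds[m]))
    for i in range(m):
        null = _rewired_adjacency(net.adjacency, weighted, swaps_per_edge,
                                  int(seeds[i]), perm_rng)
        _, cs[i] = clustering_coefficient(null, variant=clustering_variant)
        ls[i] = path_length_harmonic(distance_matrix(null))
    return NullEnsemble(clustering_means=cs, path_lengths=ls)


def small_world_params(real: GlobalMetrics, ensemble: NullEnsemble) -> SmallWorldParams:
    """gamma = C/C_null, lambda = L/L_null, sigma = gamma/lambda."""
    c_null = float(np.mean(ensemble.clustering_means))
    l_null = float(np.mean(ensemble.path_lengths))
    if c_null <= 0 or l_null <= 0:
        raise ValueError("null ensemble means must be positive")
    gamma = real.clustering_mean / c_null
    lam = real.path_length / l_null
    return SmallWorldParams(gamma=gamma, lam=lam, sigma=gamma / lam)
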