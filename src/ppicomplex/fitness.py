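"""Topological fitness of a candidate cluster.

A cluster ``C`` in a weighted network is scored by three terms:

* ``cohesiveness(C) = W_in / (W_in + W_out)`` — internal edge-weight mass
  over internal-plus-boundary mass;
* ``density(C) = 2 W_in / (|C| (|C| - 1))`` — weighted density;
* ``awm(C) = AIEW / (AIEW + ABEW)`` — average internal edge weight against
  average border edge weight (``AIEW = W_in/|E_C|``, ``ABEW = W_out/|BE_C|``);

and ``fitness(C)`` is their unweighted sum, bounded by 3 when weights lie in
[0, 1]. Degenerate 0/0 cases resolve to 0 so that degenerate clusters can
never pass the ``fitness > 0`` retention gate of the forming stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .ppi_io import WeightedPPINetwork

__all__ = [
    "ClusterScore",
    "cluster_score",
    "cohesiveness",
    "weighted_density",
    "awm",
    "fitness",
]


@dataclass(frozen=True)
class ClusterScore:
    w_in: float
    w_out: float
    n_internal_edges: int
    n_border_edges: int
    cohesiveness: float
    density: float
    awm: float
    fitness: float


def _edge_mass(C: frozenset[str] | set[str], net: WeightedPPINetwork):
    """Internal / border weight sums and edge counts for cluster ``C``."""
    members = set(C)
    w_in = 0.0
    w_out = 0.0
    n_in = 0
    n_border = 0
    for v in members:
        if v not in net:
            continue
        for u in net.neighbors(v):
            w = net.weight(v, u)
            if u in members:
                # each internal edge visited twice
                w_in += 0.5 * w
                n_in += 1
            else:
                w_out += w
                n_border += 1
    return w_in, w_out, n_in // 2, n_border


def cluster_score(C: Iterable[str], net: WeightedPPINetwork) -> ClusterScore:
    """All three fitness terms plus their ingredients for cluster ``C``."""
    members = set(C)
    if not members:
        raise ValueError("cluster is empty")
    w_in, w_out, n_in, n_border = _edge_mass(members, net)

    total = w_in + w_out
    coh = w_in / total if total > 0 else 0.0

    n = len(members)
    dens = 2.0 * w_in / (n * (n - 1)) if n >= 2 else 0.0

    aiew = w_in / n_in if n_in > 0 else 0.0
    abew = w_out / n_border if n_border > 0 else 0.0
    a = aiew / (aiew + abew) if (aiew + abew) > 0 else 0.0

    return ClusterScore(
        w_in=w_in,
        w_out=w_out,
        n_internal_edges=n_in,
        n_border_edges=n_border,
        cohesiveness=coh,
        density=dens,
        awm=a,
        fitness=dens + coh + a,
    )


def cohesiveness(C: Iterable[str], net: WeightedPPINetwork) -> float:
    return cluster_score(C, net).cohesiveness


def weighted_density(C: Iterable[str], net: WeightedPPINetwork) -> float:
    members = set(C)
    if len(members) < 2:
        logging.getLogger(__name__).warning(
            "density undefined for cluster of size %d; reporting 0", len(members)
        )
    return cluster_score(members, net).density


def awm(C: Iterable[str], net: WeightedPPINetwork) -> float:
    return cluster_score(C, net).awm


def fitness(C: Iterable[str], net: WeightedPPINetwork) -> float:
    return cluster_score(C, net).fitness
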