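"""Protein-complex core mining: seeds, local cores and Markov clustering.

Cores are mined through two complementary routes and then combined:

1. *Local* cores grow from seed proteins ranked by the weighted local
   clustering coefficient (WCC). A seed absorbs each of its neighbors that
   is both co-expressed with it (rescaled Pearson correlation above the
   ``GCE`` threshold) and co-localized (at least one shared subcellular
   compartment term). Absorbed proteins are marked and never seed later
   cores, but may still join other cores as neighbors — overlap is intrinsic
   to protein complexes.
2. *Global* cores come from Markov clustering (MCL) of the weighted graph:
   alternating expansion (matrix squaring) and inflation (entrywise power
   followed by column renormalization) of a column-stochastic flow matrix
   until the flow stabilizes.

``detect_cores`` unions the two and removes exact (set-equal) duplicates,
keeping the local copy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ppi_io import EvidenceBundle, WeightedPPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SeedRanking",
    "ProteinComplexCore",
    "normalize_expression",
    "co_expression",
    "wcc",
    "select_seeds",
    "grow_local_cores",
    "mcl_cluster",
    "detect_cores",
]


@dataclass(frozen=True)
class ProteinComplexCore:
    """A mined core: its member set and whether it came from the local or
    global (MCL) route."""

    members: frozenset[str]
    origin: str  # "local" | "global"


@dataclass
class SeedRanking:
    """Proteins ordered by descending WCC (ties broken by lexicographic ID)."""

    ranking: list[tuple[str, float]]
    ratio: float

    @property
    def seeds(self) -> list[str]:
        return [p for p, _ in self.ranking]


def normalize_expression(T: np.ndarray) -> np.ndarray:
    """Scale a raw time-course so its maximum becomes 1 (``T_i / max(T)``).

    An all-zero vector is returned unchanged with a warning (division guard).
    """
    T = np.asarray(T, dtype=float)
    if T.size < 2:
        raise ValueError("expression vector must have length >= 2")
    if np.any(T < 0):
        raise ValueError("expression values must be non-negative")
    m = T.max()
    if m == 0:
        logger.warning("all-zero expression vector; normalization skipped")
        return np.zeros_like(T)
    return T / m


def co_expression(x: np.ndarray, y: np.ndarray) -> float:
    """Co-expression value CEV(v, u): Pearson r rescaled to [0, 1] by (r+1)/2.

    Zero variance in either vector makes r undefined; it is treated as 0
    (CEV = 0.5) with a warning. Pearson correlation is invariant to the
    max-scaling normalization, so raw or normalized vectors give the same
    value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        logger.warning("zero-variance expression vector; CEV defined as 0.5")
        return 0.5
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    return (r + 1.0) / 2.0


def wcc(p: str, net: WeightedPPINetwork) -> float:
    """Weighted local clustering coefficient of protein ``p``.

    Sums the weights of all edges with both endpoints inside
    ``LN(p) = N(p) ∪ {p}`` and scales by ``sqrt(|LN|) * (|LN| - 1)``.
    Isolated proteins score 0 (denominator guard).
    """
    if p not in net:
        raise KeyError(f"protein {p!r} not in network")
    ln = net.neighbors(p)
    ln.add(p)
    k = len(ln)
    if k < 2:
        return 0.0
    total = 0.0
    for v in ln:
        for u in net.neighbors(v):
            if u in ln:
                total += 0.5 * net.weight(v, u)
    return 2.0 * total / (math.sqrt(k) * (k - 1))


def select_seeds(
    net: WeightedPPINetwork,
    ratio: float,
    wcc_scores: dict[str, float] | None = None,
) -> SeedRanking:
    """Top ``ceil(ratio * |V|)`` proteins by WCC (ratio is a fraction in (0, 1]).

    ``wcc_scores`` may carry precomputed WCC values (they depend only on the
    network, so callers evaluating many parameter settings cache them).
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if wcc_scores is None:
        wcc_scores = {p: wcc(p, net) for p in net.proteins}
    scored = sorted(
        ((p, wcc_scores[p]) for p in net.proteins),
        key=lambda t: (-t[1], t[0]),
    )
    n = math.ceil(ratio * len(scored))
    return SeedRanking(ranking=scored[:n], ratio=ratio)


def grow_local_cores(
    net: WeightedPPINetwork,
    evidence: EvidenceBundle,
    seeds: SeedRanking,
    gce: float,
    cev_cache: dict[frozenset[str], float] | None = None,
) -> list[ProteinComplexCore]:
    """Grow a local core around each unvisited seed, in ranking order.

    A neighbor ``u`` of seed ``s`` joins the core when ``CEV(s, u) > GCE``
    and ``s`` and ``u`` share at least one subcellular-compartment term.
    Absorbed proteins are marked (they never seed later cores). Cores of
    size >= 3 not already saved are kept. Seeds lacking expression or
    localization evidence are skipped with a warning.

    ``cev_cache`` optionally memoizes pairwise CEV values across calls
    (CEV does not depend on any tunable parameter).
    """
    if not 0.0 <= gce <= 1.0:
        raise ValueError(f"GCE must be in [0, 1], got {gce}")
    cache = cev_cache if cev_cache is not None else {}

    def cev(a: str, b: str) -> float | None:
        key = frozenset((a, b))
        val = cache.get(key)
        if val is None:
            xa = evidence.expression_of(a)
            xb = evidence.expression_of(b)
            if xa is None or xb is None:
                return None
            val = co_expression(xa, xb)
            cache[key] = val
        return val

    visited: set[str] = set()
    saved: set[frozenset[str]] = set()
    cores: list[ProteinComplexCore] = []
    for s in seeds.seeds:
        if s in visited:
            continue
        sld_s = evidence.localization_of(s)
        if evidence.expression_of(s) is None or not sld_s:
            logger.warning("seed %s lacks expression or localization data; skipped", s)
            continue
        visited.add(s)
        core = {s}
        for u in sorted(net.neighbors(s)):
            val = cev(s, u)
            if val is None:
                continue
            if val > gce and sld_s & evidence.localization_of(u):
                core.add(u)
                visited.add(u)
        if len(core) >= 3:
            key = frozenset(core)
            if key not in saved:
                saved.add(key)
                cores.append(ProteinComplexCore(members=key, origin="local"))
    return cores


def mcl_cluster(
    net: WeightedPPINetwork,
    inflate: float,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> list[ProteinComplexCore]:
    """Markov clustering of the weighted network.

    The flow matrix starts from the weight matrix with unit self-loops,
    column-normalized. Each round squares the matrix (expansion), raises it
    entrywise to ``inflate`` (inflation), prunes entries below ``prune`` and
    renormalizes columns, until the largest entry change drops below ``tol``
    or ``max_iter`` rounds pass (then the current clustering is returned with
    a warning). Clusters are the connected components of the converged flow's
    support — a partition of the nodes. Singleton components are dropped
    (they can never reach the size-3 retention gate).
    """
    if inflate <= 0:
        raise ValueError(f"inflate must be positive, got {inflate}")
    nodes = sorted(net.proteins)
    n = len(nodes)
    if n == 0:
        return []
    index = {p: i for i, p in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, w in net.edges():
        i, j = index[u], index[v]
        M[i, j] = w
        M[j, i] = w
    np.fill_diagonal(M, 1.0)  # self-loop weight 1

    def _normalize(A: np.ndarray) -> np.ndarray:
        s = A.sum(axis=0)
        s[s == 0] = 1.0
        return A / s

    M = _normalize(M)
    converged = False
    for _ in range(max_iter):
        new = M @ M
        new = np.power(new, inflate)
        new[new < prune] = 0.0
        new = _normalize(new)
        if np.max(np.abs(new - M)) < tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    support = (M > prune) | (M.T > prune)
    # connected components of the flow support
    seen = np.zeros(n, dtype=bool)
    cores: list[ProteinComplexCore] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(support[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        if len(comp) > 1:
            cores.append(
                ProteinComplexCore(
                    members=frozenset(nodes[i] for i in comp), origin="global"
                )
            )
    cores.sort(key=lambda c: sorted(c.members))
    return cores


def detect_cores(
    net: WeightedPPINetwork,
    evidence: EvidenceBundle,
    gce: float,
    inflate: float,
    ratio: float,
    cev_cache: dict[frozenset[str], float] | None = None,
    wcc_scores: dict[str, float] | None = None,
    mcl_kwargs: dict | None = None,
) -> list[ProteinComplexCore]:
    """Union of local and global cores with exact-duplicate removal.

    When a local and a global core have identical membership the local copy
    is kept. ``wcc_scores`` and ``cev_cache`` allow reuse of the
    parameter-independent ingredients across evaluations.
    """
    seed_ranking = select_seeds(net, ratio, wcc_scores=wcc_scores)
    local = grow_local_cores(net, evidence, seed_ranking, gce, cev_cache=cev_cache)
    global_ = mcl_cluster(net, inflate, **(mcl_kwargs or {}))
    seen = {c.members for c in local}
    out = list(local)
    for c in global_:
        if c.members not in seen:
            seen.add(c.members)
            out.append(c)
    return out
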