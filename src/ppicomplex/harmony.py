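"""Adaptive harmony search over the detector's three parameters.

The detection pipeline depends on three tunables: the gene co-expression
threshold ``GCE`` (0.6–0.9), the MCL inflation exponent ``inflate``
(0.5–4.0) and the seed fraction ``ratio`` (0.5–0.9). The objective is the
summed fitness of the filtered complexes the pipeline produces,

    OF_fitness(GCE, inflate, ratio) = sum_i fitness(C_i),

maximized by a harmony search whose control parameters adapt over time:

    HMCR_i = HMCR_min + i/Maxiter * (HMCR_max - HMCR_min)
    PAR_i  = PAR_max  - i/Maxiter * (PAR_max  - PAR_min)
    FW_i   = FW_min + (FW_max - FW_min)
             * (fitnessmax - currentfitness) * (Maxiter - i)
             / ((fitnessmax - fitnessmin) * Maxiter)

with HMCR in 0.7–0.95, PAR in 0.1–0.5, FW in 0.01–0.1, a memory of 30
harmonies and 300 iterations by default. Memory harmonies are drawn by
roulette-wheel selection proportional to their objective; the fret-width
perturbation is scaled by each parameter's range width (the parameters span
very different scales — a dimensionless step would barely move ``inflate``).
The worst memory slot is replaced only by a strictly better improvisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .filtering import filter_complexes
from .fitness import fitness as cluster_fitness
from .forming import form_complexes
from .mining import detect_cores
from .ppi_io import ComplexSet, EvidenceBundle, WeightedPPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterBounds",
    "ScheduleConstants",
    "Harmony",
    "HarmonyMemory",
    "of_fitness",
    "make_objective",
    "adaptive_params",
    "roulette_select",
    "improvise",
    "optimize",
    "OptimizeResult",
]


@dataclass(frozen=True)
class ParameterBounds:
    """Search ranges of the three pipeline parameters."""

    gce: tuple[float, float] = (0.6, 0.9)
    inflate: tuple[float, float] = (0.5, 4.0)
    ratio: tuple[float, float] = (0.5, 0.9)

    def clamp(self, gce: float, inflate: float, ratio: float) -> tuple[float, float, float]:
        return (
            min(max(gce, self.gce[0]), self.gce[1]),
            min(max(inflate, self.inflate[0]), self.inflate[1]),
            min(max(ratio, self.ratio[0]), self.ratio[1]),
        )

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        return (
            rng.uniform(*self.gce),
            rng.uniform(*self.inflate),
            rng.uniform(*self.ratio),
        )

    @property
    def widths(self) -> tuple[float, float, float]:
        return (
            self.gce[1] - self.gce[0],
            self.inflate[1] - self.inflate[0],
            self.ratio[1] - self.ratio[0],
        )


@dataclass(frozen=True)
class ScheduleConstants:
    """Adaptive-schedule endpoints of the search."""

    hmcr: tuple[float, float] = (0.7, 0.95)  # (min, max)
    par: tuple[float, float] = (0.1, 0.5)
    fw: tuple[float, float] = (0.01, 0.1)
    hms: int = 30
    maxiter: int = 300


@dataclass
class Harmony:
    """One parameter triple with its objective value (None if unevaluated)."""

    gce: float
    inflate: float
    ratio: float
    objective: float | None = None

    def params(self) -> tuple[float, float, float]:
        return (self.gce, self.inflate, self.ratio)


@dataclass
class HarmonyMemory:
    harmonies: list[Harmony] = field(default_factory=list)

    def objectives(self) -> np.ndarray:
        return np.array([h.objective for h in self.harmonies], dtype=float)

    def best(self) -> Harmony:
        """Highest objective; ties resolve to the older (earlier) harmony."""
        obj = self.objectives()
        return self.harmonies[int(np.argmax(obj))]

    def worst_index(self) -> int:
        obj = self.objectives()
        return int(np.argmin(obj))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def make_objective(
    net: WeightedPPINetwork,
    evidence: EvidenceBundle,
    annotations: dict[str, set[str]] | None = None,
    max_rounds: int = 2,
    stop_terms: Sequence[str] = (),
    memo_decimals: int = 4,
) -> Callable[[float, float, float], tuple[float, ComplexSet]]:
    """Build the memoized pipeline objective for one (network, evidence) pair.

    The returned callable runs detect → form → filter at the given
    parameters and returns ``(OF_fitness, filtered complexes)``. Results are
    memoized on the parameters rounded to ``memo_decimals`` (below the
    smallest fret-width step, so the cache never hides a genuine move); the
    expensive parameter-independent ingredients (WCC ranking, pairwise CEV)
    are shared across evaluations.
    """
    annots = annotations if annotations is not None else evidence.annotations
    cev_cache: dict[frozenset[str], float] = {}
    from .mining import wcc as _wcc

    wcc_scores = {p: _wcc(p, net) for p in net.proteins}
    memo: dict[tuple[float, float, float], tuple[float, ComplexSet]] = {}

    def objective(gce: float, inflate: float, ratio: float) -> tuple[float, ComplexSet]:
        key = (round(gce, memo_decimals), round(inflate, memo_decimals),
               round(ratio, memo_decimals))
        hit = memo.get(key)
        if hit is not None:
            return hit
        cores = detect_cores(
            net, evidence, gce, inflate, ratio,
            cev_cache=cev_cache, wcc_scores=wcc_scores,
        )
        candidates = form_complexes(cores, net, max_rounds=max_rounds)
        filtered = filter_complexes(candidates, annots, stop_terms=stop_terms)
        of = sum(cluster_fitness(c, net) for c in filtered)
        memo[key] = (of, filtered)
        return memo[key]

    return objective


def of_fitness(
    net: WeightedPPINetwork,
    evidence: EvidenceBundle,
    gce: float,
    inflate: float,
    ratio: float,
    **kwargs,
) -> float:
    """One-shot objective value (see :func:`make_objective` for caching)."""
    of, _ = make_objective(net, evidence, **kwargs)(gce, inflate, ratio)
    return of


# ---------------------------------------------------------------------------
# adaptive schedule
# ---------------------------------------------------------------------------

def adaptive_params(
    i: int,
    fitnessmax: float,
    fitnessmin: float,
    currentfitness: float,
    consts: ScheduleConstants = ScheduleConstants(),
) -> tuple[float, float, float]:
    """(HMCR_i, PAR_i, FW_i) at iteration ``i`` of ``consts.maxiter``.

    When the memory has collapsed (fitnessmax == fitnessmin) the fret width
    degenerates to its minimum.
    """
    if not 0 <= i <= consts.maxiter:
        raise ValueError(f"iteration {i} outside [0, {consts.maxiter}]")
    if fitnessmax < fitnessmin:
        raise ValueError("fitnessmax < fitnessmin")
    t = i / consts.maxiter
    # convex combinations (endpoint-exact form of min + t*(max-min))
    hmcr = (1.0 - t) * consts.hmcr[0] + t * consts.hmcr[1]
    par = (1.0 - t) * consts.par[1] + t * consts.par[0]
    spread = fitnessmax - fitnessmin
    if spread == 0:
        fw = consts.fw[0]
    else:
        fw = consts.fw[0] + (consts.fw[1] - consts.fw[0]) * (
            (fitnessmax - currentfitness) * (consts.maxiter - i) / (spread * consts.maxiter)
        )
    return hmcr, par, fw


def roulette_select(mem: HarmonyMemory, rng: np.random.Generator) -> Harmony:
    """Draw a memory harmony with probability proportional to its objective.

    All objectives are non-negative; an all-zero memory falls back to a
    uniform draw.
    """
    if not mem.harmonies:
        raise ValueError("harmony memory is empty")
    obj = mem.objectives()
    total = obj.sum()
    if total <= 0:
        idx = rng.integers(len(obj))
    else:
        idx = rng.choice(len(obj), p=obj / total)
    return mem.harmonies[int(idx)]


def _perturb(
    params: tuple[float, float, float],
    fw: float,
    bounds: ParameterBounds,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    widths = bounds.widths
    moved = tuple(
        p + rng.uniform(-fw, fw) * w for p, w in zip(params, widths)
    )
    return bounds.clamp(*moved)


def improvise(
    mem: HarmonyMemory,
    rng: np.random.Generator,
    i: int,
    bounds: ParameterBounds = ParameterBounds(),
    consts: ScheduleConstants = ScheduleConstants(),
) -> Harmony:
    """Improvise one new (unevaluated) harmony at iteration ``i``.

    With probability ``HMCR_i`` a memory harmony is taken by roulette
    selection and, with probability ``PAR_i``, all three of its parameters
    are perturbed by ``U(-FW_i, FW_i)`` scaled by the parameter's range
    width. Otherwise a fresh harmony is sampled uniformly from the ranges
    and always receives the same fret-width perturbation. All parameters are
    clamped to their ranges.
    """
    obj = mem.objectives()
    fmax, fmin = float(obj.max()), float(obj.min())
    r1 = rng.uniform()
    hmcr_i, par_i, _ = adaptive_params(i, fmax, fmin, fmax, consts)
    if r1 < hmcr_i:
        chosen = roulette_select(mem, rng)
        _, _, fw_i = adaptive_params(i, fmax, fmin, float(chosen.objective), consts)
        params = chosen.params()
        r2 = rng.uniform()
        if r2 < par_i:
            params = _perturb(params, fw_i, bounds, rng)
        else:
            params = bounds.clamp(*params)
    else:
        # a random harmony explores; it gets the widest fret (treated as
        # sitting at the memory's minimum fitness)
        _, _, fw_i = adaptive_params(i, fmax, fmin, fmin, consts)
        params = bounds.sample(rng)
        params = _perturb(params, fw_i, bounds, rng)
    return Harmony(*params)


@dataclass
class OptimizeResult:
    best: Harmony
    complexes: ComplexSet
    trace: pd.DataFrame
    memory: HarmonyMemory


def optimize(
    objective: Callable[[float, float, float], tuple[float, ComplexSet]],
    seed: int,
    bounds: ParameterBounds = ParameterBounds(),
    consts: ScheduleConstants = ScheduleConstants(),
) -> OptimizeResult:
    """Run the adaptive harmony search against ``objective``.

    ``objective`` maps a parameter triple to ``(OF_fitness, complexes)``;
    see :func:`make_objective`. The memory is initialized with ``hms``
    uniform-random harmonies; each of the ``maxiter`` iterations improvises
    one harmony and replaces the worst memory slot iff the newcomer is
    strictly better (ties keep the incumbent, so the best objective trace is
    non-decreasing). Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    mem = HarmonyMemory()
    for _ in range(consts.hms):
        h = Harmony(*bounds.sample(rng))
        h.objective, _ = objective(*h.params())
        mem.harmonies.append(h)

    rows = []
    for i in range(1, consts.maxiter + 1):
        new = improvise(mem, rng, i, bounds, consts)
        new.objective, _ = objective(*new.params())
        worst = mem.worst_index()
        if new.objective > mem.harmonies[worst].objective:
            mem.harmonies[worst] = new
        best = mem.best()
        rows.append(
            {
                "iteration": i,
                "best_objective": best.objective,
                "gce": best.gce,
                "inflate": best.inflate,
                "ratio": best.ratio,
            }
        )
    best = mem.best()
    _, complexes = objective(*best.params())
    trace = pd.DataFrame(rows)
    return OptimizeResult(best=best, complexes=complexes, trace=trace, memory=mem)
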