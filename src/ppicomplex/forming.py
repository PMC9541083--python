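"""Complex forming: attach peripheral proteins to cores, prune weak members.

Each mined core is refined by alternating two greedy passes for at most two
rounds (protein complexes have small diameter, so two rounds suffice):

* *expansion* — repeatedly insert the neighboring protein with the highest
  attachment score, but only while the insertion strictly increases the
  cluster fitness;
* *contraction* — while the cluster has at least 4 members, repeatedly
  remove the member with the lowest leave-one-out attachment score, but only
  while the removal strictly increases fitness.

Strict inequality on every accepted move guarantees termination (fitness is
bounded by 3) and makes the procedure deterministic together with the
lexicographic tie-break on protein IDs. Candidates are retained iff their
fitness is positive and they have at least 3 members; exact duplicates are
removed from the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .fitness import fitness
from .mining import ProteinComplexCore
from .ppi_io import ComplexSet, WeightedPPINetwork

__all__ = [
    "CandidateComplex",
    "attach_score",
    "expand_once",
    "contract_once",
    "form_complexes",
]


@dataclass
class CandidateComplex:
    members: set[str]
    fitness: float
    rounds_used: int = 0


def attach_score(v: str, core: Iterable[str], net: WeightedPPINetwork) -> float:
    """Total edge weight from ``v`` into ``core``, divided by ``|core|``."""
    members = set(core)
    if v in members:
        raise ValueError(f"protein {v!r} is already a member of the core")
    if not members:
        raise ValueError("core is empty")
    total = sum(net.weight(v, u) for u in net.neighbors(v) if u in members)
    return total / len(members)


def _neighborhood(members: set[str], net: WeightedPPINetwork) -> set[str]:
    out: set[str] = set()
    for v in members:
        if v in net:
            out |= net.neighbors(v)
    return out - members


def expand_once(cpc: CandidateComplex, net: WeightedPPINetwork) -> tuple[CandidateComplex, bool]:
    """Greedy insertion pass; returns the candidate and whether it changed."""
    changed = False
    while True:
        neighborhood = _neighborhood(cpc.members, net)
        if not neighborhood:
            break
        node_max = min(
            neighborhood,
            key=lambda v: (-attach_score(v, cpc.members, net), v),
        )
        new_fitness = fitness(cpc.members | {node_max}, net)
        if new_fitness > cpc.fitness:
            cpc.members.add(node_max)
            cpc.fitness = new_fitness
            changed = True
        else:
            break
    return cpc, changed


def contract_once(cpc: CandidateComplex, net: WeightedPPINetwork) -> tuple[CandidateComplex, bool]:
    """Greedy removal pass; returns the candidate and whether it changed."""
    changed = False
    while len(cpc.members) >= 4:
        node_min = min(
            cpc.members,
            key=lambda v: (attach_score(v, cpc.members - {v}, net), v),
        )
        new_fitness = fitness(cpc.members - {node_min}, net)
        if new_fitness > cpc.fitness:
            cpc.members.discard(node_min)
            cpc.fitness = new_fitness
            changed = True
        else:
            break
    return cpc, changed


def form_complex(
    core: Iterable[str], net: WeightedPPINetwork, max_rounds: int = 2
) -> CandidateComplex:
    """Refine one core through alternating expansion/contraction rounds."""
    members = set(core)
    cpc = CandidateComplex(members=members, fitness=fitness(members, net))
    for round_no in range(1, max_rounds + 1):
        cpc, grew = expand_once(cpc, net)
        cpc, shrank = contract_once(cpc, net)
        cpc.rounds_used = round_no
        if not (grew or shrank):
            break
    return cpc


def form_complexes(
    cores: Sequence[ProteinComplexCore | Iterable[str]],
    net: WeightedPPINetwork,
    max_rounds: int = 2,
) -> ComplexSet:
    """Refine every core and keep candidates with fitness > 0 and size >= 3."""
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for core in cores:
        members = core.members if isinstance(core, ProteinComplexCore) else core
        cpc = form_complex(members, net, max_rounds=max_rounds)
        if cpc.fitness > 0 and len(cpc.members) >= 3:
            key = frozenset(cpc.members)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return ComplexSet(out)
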