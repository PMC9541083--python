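"""Edge reliability weights from functional-annotation similarity.

Each interacting pair is scored per GO branch (cellular component,
biological process, molecular function) and the three branch scores are
averaged into one reliability weight in [0, 1]:

    w(v, u) = (sim_CC(v, u) + sim_BP(v, u) + sim_MF(v, u)) / 3

The branch scorer is pluggable. The built-in default is term-set Jaccard
similarity per branch; a branch in which either protein is unannotated
scores 0. Weights produced by an external semantic-similarity tool can be
loaded verbatim from a 3-column TSV instead (``precomputed``), which is the
route for topology-aware scorers such as TCSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .ppi_io import DataError, EvidenceBundle, WeightedPPINetwork, read_network

__all__ = [
    "BranchSimilarity",
    "SCORERS",
    "register_scorer",
    "branch_similarity",
    "combine",
    "weight_network",
    "load_precomputed_weights",
]

BRANCHES = ("cc", "bp", "mf")

# Topology cutoffs reported for the TCSS tool on yeast (provenance only;
# TCSS itself is consumed via precomputed weights, not re-implemented):
# CC 2.4, BP 3.5, MF 3.3.
TCSS_TOPOLOGY_CUTOFFS = {"cc": 2.4, "bp": 3.5, "mf": 3.3}


@dataclass(frozen=True)
class BranchSimilarity:
    """Per-branch similarity of one protein pair; each component in [0, 1]."""

    cc: float
    bp: float
    mf: float

    def __post_init__(self) -> None:
        for name in BRANCHES:
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} similarity {x} outside [0, 1]")


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


ScorerFunc = Callable[[set[str], set[str]], float]

SCORERS: dict[str, ScorerFunc] = {"jaccard": _jaccard}


def register_scorer(name: str, func: ScorerFunc) -> None:
    """Register a per-branch term-set scorer under ``name``."""
    SCORERS[name] = func


def _resolve_scorer(scorer: str | ScorerFunc) -> ScorerFunc:
    if callable(scorer):
        return scorer
    try:
        return SCORERS[scorer]
    except KeyError:
        raise DataError(
            f"unknown scorer {scorer!r}; registered scorers: {sorted(SCORERS)}"
        ) from None


def branch_similarity(
    v: str,
    u: str,
    branch_annotations: Mapping[str, Mapping[str, set[str]]],
    scorer: str | ScorerFunc = "jaccard",
) -> BranchSimilarity:
    """Score the pair ``(v, u)`` in each GO branch.

    ``branch_annotations`` maps branch name (``cc``/``bp``/``mf``) to a
    protein→term-set map. A protein absent from a branch contributes an empty
    term set, which scores 0 in that branch.
    """
    func = _resolve_scorer(scorer)
    scores = {}
    for branch in BRANCHES:
        terms = branch_annotations.get(branch, {})
        scores[branch] = func(set(terms.get(v, ())), set(terms.get(u, ())))
    return BranchSimilarity(**scores)


def combine(bs: BranchSimilarity) -> float:
    """Arithmetic mean of the three branch similarities."""
    return (bs.cc + bs.bp + bs.mf) / 3.0


def weight_network(
    net: WeightedPPINetwork,
    evidence: EvidenceBundle,
    scorer: str | ScorerFunc = "jaccard",
) -> WeightedPPINetwork:
    """Replace every edge weight by the combined branch similarity.

    Topology is unchanged; zero-weight edges are retained (downstream
    cohesiveness/awm handle zeros; pruning would discard topology the
    forming stage can still use).
    """
    out = net.copy()
    for a, b, _ in net.edges():
        bs = branch_similarity(a, b, evidence.branch_annotations, scorer=scorer)
        out.set_weight(a, b, combine(bs))
    return out


def load_precomputed_weights(
    net: WeightedPPINetwork, path, missing: str = "error"
) -> WeightedPPINetwork:
    """Load per-edge weights verbatim from a ``proteinA proteinB weight`` TSV.

    ``missing`` controls edges of ``net`` absent from the file: ``"error"``
    (default) raises, ``"zero"`` assigns weight 0.
    """
    if missing not in ("error", "zero"):
        raise ValueError("missing must be 'error' or 'zero'")
    table = read_network(path, default_weight=1.0)
    out = net.copy()
    for a, b, _ in net.edges():
        if table.has_edge(a, b):
            out.set_weight(a, b, table.weight(a, b))
        elif missing == "error":
            raise DataError(f"precomputed weight file {path} is missing edge {a!r}-{b!r}")
        else:
            out.set_weight(a, b, 0.0)
    return out
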