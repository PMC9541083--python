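"""Readers, writers and containers for PPI networks, evidence and complex sets.

The on-disk formats are deliberately plain text:

* edge lists — whitespace-separated ``proteinA proteinB [weight]``;
* expression matrices — ``protein  t1 t2 ... tn``;
* localization / annotation maps — two-column ``protein  term`` (annotation
  files may instead be GAF 2.x, of which only the object-symbol, GO-ID and
  aspect columns are consumed);
* complex sets — one complex per line, members whitespace-separated (the
  de-facto format of MCL-family tools).

Protein identifiers are opaque, case-sensitive strings; no name mapping is
attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "WeightedPPINetwork",
    "ComplexSet",
    "EvidenceBundle",
    "NetworkSummary",
    "read_network",
    "write_network",
    "network_summary",
    "density",
    "read_evidence",
    "read_expression",
    "read_term_map",
    "read_complexes",
    "write_complexes",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


class WeightedPPINetwork:
    """Undirected PPI graph ``G = (V, E, W)`` with reliability weights in [0, 1].

    Thin wrapper over :class:`networkx.Graph` that enforces the container
    invariants (no self-loops, unordered edge uniqueness, finite weights in
    [0, 1]) and exposes the vocabulary used throughout the package:
    ``proteins``, ``edges``, ``weight(v, u)`` and ``neighbors(v)`` (``N(v)``).
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph()
        if graph is not None:
            for u, v, data in graph.edges(data=True):
                self._check_edge(u, v, data.get("weight", 1.0))
                g.add_edge(u, v, weight=float(data.get("weight", 1.0)))
            g.add_nodes_from(graph.nodes())
        self._g = g

    @staticmethod
    def _check_edge(u, v, w) -> None:
        if u == v:
            raise DataError(f"self-interaction {u!r}-{v!r} not allowed")
        w = float(w)
        if not math.isfinite(w) or not 0.0 <= w <= 1.0:
            raise DataError(f"weight {w!r} for edge {u!r}-{v!r} outside [0, 1]")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "WeightedPPINetwork":
        net = cls()
        for u, v, w in edges:
            net.add_edge(u, v, w)
        for n in nodes:
            net._g.add_node(n)
        return net

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        self._check_edge(u, v, weight)
        self._g.add_edge(u, v, weight=float(weight))

    # -- queries -----------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes())

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str, default: float = 0.0) -> float:
        data = self._g.get_edge_data(u, v)
        return data["weight"] if data is not None else default

    def neighbors(self, v: str) -> set[str]:
        """``N(v)`` — the immediate interaction partners of ``v``."""
        return set(self._g.neighbors(v))

    def set_weight(self, u: str, v: str, weight: float) -> None:
        if not self._g.has_edge(u, v):
            raise DataError(f"edge {u!r}-{v!r} not in network")
        self._check_edge(u, v, weight)
        self._g[u][v]["weight"] = float(weight)

    def copy(self) -> "WeightedPPINetwork":
        return WeightedPPINetwork(self._g)


@dataclass
class ComplexSet:
    """An ordered collection of protein sets (reference or predicted complexes)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        for i, c in enumerate(self.complexes):
            if not c:
                raise DataError(f"complex {i} is empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def dedupe(self) -> tuple["ComplexSet", int]:
        """Drop set-equal duplicates, keeping first occurrence.

        Returns the deduplicated set and the number of redundant complexes
        removed. Reading never deduplicates silently; callers opt in.
        """
        seen: set[frozenset[str]] = set()
        kept: list[frozenset[str]] = []
        for c in self.complexes:
            if c not in seen:
                seen.add(c)
                kept.append(c)
        return ComplexSet(kept), len(self.complexes) - len(kept)

    def all_proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out


@dataclass
class EvidenceBundle:
    """Per-protein biological evidence used by the local core-mining stage.

    ``expression`` maps a protein to its time-course vector (equal length
    across proteins), ``localization`` to its set of subcellular-compartment
    terms and ``annotations`` to its set of functional terms. Missing proteins
    simply have no entry; accessors return empty evidence for them.
    ``branch_annotations`` optionally splits annotations by GO branch
    (``cc``/``bp``/``mf``) when the source file carries aspect information.
    """

    expression: dict[str, np.ndarray] = field(default_factory=dict)
    localization: dict[str, set[str]] = field(default_factory=dict)
    annotations: dict[str, set[str]] = field(default_factory=dict)
    branch_annotations: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.expression.values()}
        if len(lengths) > 1:
            raise DataError(f"expression vectors have unequal lengths: {sorted(lengths)}")
        if lengths and lengths.pop() < 2:
            raise DataError("expression vectors must have at least 2 time points")
        self.expression = {k: np.asarray(v, dtype=float) for k, v in self.expression.items()}

    def expression_of(self, protein: str) -> np.ndarray | None:
        return self.expression.get(protein)

    def localization_of(self, protein: str) -> set[str]:
        return self.localization.get(protein, set())

    def annotations_of(self, protein: str) -> set[str]:
        return self.annotations.get(protein, set())


class NetworkSummary(NamedTuple):
    n_proteins: int
    n_interactions: int
    density: float


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(path, default_weight: float = 1.0) -> WeightedPPINetwork:
    """Read a 2- or 3-column edge list into a :class:`WeightedPPINetwork`.

    Self-interactions are removed and duplicate unordered pairs collapsed,
    keeping the maximum weight (a conservative reliability choice). Missing
    third columns take ``default_weight``. Malformed lines and out-of-range
    weights raise :class:`DataError` naming the offending line.
    """
    best: dict[frozenset[str], float] = {}
    n_self = 0
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) == 1:
                raise DataError(f"{path}: line {lineno}: expected 2 or 3 columns, got 1")
            if len(fields) > 3:
                raise DataError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise DataError(
                        f"{path}: line {lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
            else:
                w = float(default_weight)
            if not math.isfinite(w) or not 0.0 <= w <= 1.0:
                raise DataError(f"{path}: line {lineno}: weight {w} outside [0, 1]")
            if u == v:
                n_self += 1
                continue
            key = frozenset((u, v))
            if key in best:
                n_dup += 1
                best[key] = max(best[key], w)
            else:
                best[key] = w
    net = WeightedPPINetwork()
    for key, w in best.items():
        u, v = sorted(key)
        net.add_edge(u, v, w)
    logger.info(
        "read %s: %d proteins, %d interactions (%d self-interactions and "
        "%d duplicate pairs eliminated)",
        path, len(net), net.n_edges, n_self, n_dup,
    )
    return net


def write_network(net: WeightedPPINetwork, path) -> None:
    """Write a 3-column edge list (sorted for reproducibility)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in sorted((tuple(sorted((a, b))) + (w,)) for a, b, w in net.edges()):
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def density(n_nodes: int, n_edges: int) -> float:
    """Unweighted graph density ``2|E| / (|V|(|V|-1))``."""
    if n_nodes < 2:
        logger.warning("density undefined for %d node(s); reporting 0", n_nodes)
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def network_summary(net: WeightedPPINetwork) -> NetworkSummary:
    """Node count, edge count and unweighted density of the network."""
    return NetworkSummary(len(net), net.n_edges, density(len(net), net.n_edges))


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def read_expression(path) -> dict[str, np.ndarray]:
    """Read a protein-by-timepoint matrix; rows must share one arity."""
    out: dict[str, np.ndarray] = {}
    arity: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            protein, raw = fields[0], fields[1:]
            if arity is None:
                arity = len(raw)
            elif len(raw) != arity:
                raise DataError(
                    f"{path}: line {lineno}: ragged row ({len(raw)} values, expected {arity})"
                )
            try:
                out[protein] = np.array([float(x) for x in raw])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: non-numeric expression value") from exc
    return out


_GAF_ASPECTS = {"C": "cc", "P": "bp", "F": "mf"}


def _looks_like_gaf(path) -> bool:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, dict[str, set[str]]]]:
    """Read a protein→term map from a two/three-column TSV or a GAF 2.x file.

    For GAF input only the DB-object symbol (column 3), GO ID (column 5) and
    aspect (column 9) are used. Returns the union map plus a per-branch map
    (empty branch dicts when the source has no branch information).
    """
    union: dict[str, set[str]] = {}
    branches: dict[str, dict[str, set[str]]] = {"cc": {}, "bp": {}, "mf": {}}
    if _looks_like_gaf(path):
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    continue
                protein, term, aspect = cols[2], cols[4], cols[8]
                union.setdefault(protein, set()).add(term)
                branch = _GAF_ASPECTS.get(aspect)
                if branch is not None:
                    branches[branch].setdefault(protein, set()).add(term)
        return union, branches
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 2:
                raise DataError(f"{path}: line {lineno}: expected at least 2 columns")
            protein, term = fields[0], fields[1]
            union.setdefault(protein, set()).add(term)
            if len(fields) >= 3:
                branch = fields[2].lower()
                if branch in branches:
                    branches[branch].setdefault(protein, set()).add(term)
    return union, branches


def read_evidence(expr_path, loc_path, annot_path) -> EvidenceBundle:
    """Assemble an :class:`EvidenceBundle` from the three evidence files."""
    expression = read_expression(expr_path) if expr_path is not None else {}
    localization, _ = read_term_map(loc_path) if loc_path is not None else ({}, {})
    annotations, branch = read_term_map(annot_path) if annot_path is not None else ({}, {})
    return EvidenceBundle(
        expression=expression,
        localization=localization,
        annotations=annotations,
        branch_annotations=branch,
    )


# ---------------------------------------------------------------------------
# complex sets
# ---------------------------------------------------------------------------

def read_complexes(path) -> ComplexSet:
    """One complex per line, members whitespace-separated; empty lines skipped."""
    complexes: list[frozenset[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            members = line.split()
            if not members:
                logger.warning("%s: line %d is empty; skipped", path, lineno)
                continue
            complexes.append(frozenset(members))
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c)) + "\n")
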