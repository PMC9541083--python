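"""Functional-coherence filtering of candidate complexes.

For each candidate complex the functional annotation term shared by the most
members is found (``max_common_term``); only the members carrying that term
are kept, and the filtered complex survives iff it still has at least 3
members. The result is a set of complexes whose members all share one
functional term. Ties on coverage are broken by lexicographically smallest
term for determinism. A stop-term list can exclude uninformative (e.g. root)
terms from consideration.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

from .ppi_io import ComplexSet

__all__ = ["max_common_term", "filter_complexes"]


def max_common_term(
    C: Iterable[str],
    annotations: Mapping[str, set[str]],
    stop_terms: Iterable[str] = (),
) -> tuple[str | None, int]:
    """Term annotating the most members of ``C`` and its coverage count.

    Returns ``(None, 0)`` when no member carries any (non-stop) term.
    """
    members = set(C)
    if not members:
        raise ValueError("complex is empty")
    stop = set(stop_terms)
    counts: Counter[str] = Counter()
    for u in members:
        for term in annotations.get(u, ()):
            if term not in stop:
                counts[term] += 1
    if not counts:
        return None, 0
    term = min(counts, key=lambda t: (-counts[t], t))
    return term, counts[term]


def filter_complexes(
    cs: ComplexSet,
    annotations: Mapping[str, set[str]],
    stop_terms: Iterable[str] = (),
    min_size: int = 3,
) -> ComplexSet:
    """Keep, per complex, only the members sharing its most-common term.

    Filtered complexes below ``min_size`` are dropped; exact duplicates are
    removed at the end. Filtering is idempotent.
    """
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for C in cs:
        term, _ = max_common_term(C, annotations, stop_terms)
        if term is None:
            continue
        fpc = frozenset(u for u in C if term in annotations.get(u, ()))
        if len(fpc) >= min_size and fpc not in seen:
            seen.add(fpc)
            out.append(fpc)
    return ComplexSet(out)
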