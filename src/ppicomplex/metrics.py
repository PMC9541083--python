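"""Evaluation of predicted complexes against a reference catalog.

``S`` denotes the reference (standard) complexes and ``D`` the detected
ones. The headline metrics are:

* **F-measure** — harmonic mean of precision (``N_im/|D|``) and recall
  (``N_sm/|S|``), where a pair matches when its neighborhood affinity
  ``NA(S_i, D_j) = |S_i ∩ D_j|² / (|S_i| |D_j|)`` reaches ``ω = 0.20``;
* **ACC** — geometric mean of Sn (row-max overlap over reference sizes) and
  PPV (column-max overlap over total overlap);
* **MMR** — the best NA achieved for each reference complex, averaged;
* **Frac** — fraction of reference complexes matched at ``ω = 0.25``;
* **Jaccard** — harmonic combination of the size-weighted best per-complex
  Jaccard indices of the two sides;
* **total score** — the plain sum of the five.

Per-complex functional enrichment uses the hypergeometric upper tail:
``p = P(X >= k)`` for a complex of size ``|C|`` overlapping a functional
group ``F`` in ``k`` proteins out of a background of ``|V|``; a complex is
called biologically significant when its smallest p-value over all groups is
below 0.01 (no multiple-testing correction, matching common usage of
complex-enrichment tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .ppi_io import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "EnrichmentResult",
    "neighborhood_affinity",
    "f_measure",
    "acc",
    "mmr",
    "frac",
    "jaccard_composite",
    "total_score",
    "evaluate",
    "complex_pvalue",
    "enrichment_report",
    "ENRICHMENT_BINS",
]

OMEGA_MATCH = 0.20  # NA threshold for F-measure match counting
OMEGA_FRAC = 0.25  # NA threshold for Frac
SIGNIFICANCE = 0.01


def neighborhood_affinity(S_i: Iterable[str], D_j: Iterable[str]) -> float:
    """``NA(S_i, D_j) = |S_i ∩ D_j|² / (|S_i| × |D_j|)``; symmetric, in [0, 1]."""
    a, b = set(S_i), set(D_j)
    if not a or not b:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _na_matrix(S: ComplexSet, D: ComplexSet) -> np.ndarray:
    na = np.zeros((len(S), len(D)))
    for i, s in enumerate(S):
        for j, d in enumerate(D):
            na[i, j] = neighborhood_affinity(s, d)
    return na


def f_measure(
    S: ComplexSet, D: ComplexSet, omega: float = OMEGA_MATCH
) -> tuple[float, float, float]:
    """(precision, recall, F) under NA-threshold matching at ``omega``."""
    if len(S) == 0 or len(D) == 0:
        logger.warning("empty complex set; F-measure reported as 0")
        return 0.0, 0.0, 0.0
    na = _na_matrix(S, D)
    n_sm = int(np.sum(na.max(axis=1) >= omega))
    n_im = int(np.sum(na.max(axis=0) >= omega))
    recall = n_sm / len(S)
    precision = n_im / len(D)
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def acc(S: ComplexSet, D: ComplexSet) -> tuple[float, float, float]:
    """(Sn, PPV, ACC) from the overlap table ``T_ij = |S_i ∩ D_j|``."""
    T = np.zeros((len(S), len(D)))
    for i, s in enumerate(S):
        for j, d in enumerate(D):
            T[i, j] = len(set(s) & set(d))
    size_s = sum(len(s) for s in S)
    sn = float(T.max(axis=1).sum()) / size_s if len(D) and size_s else 0.0
    t_total = float(T.sum())
    ppv = float(T.max(axis=0).sum()) / t_total if t_total > 0 else 0.0
    return sn, ppv, float(np.sqrt(sn * ppv))


def mmr(S: ComplexSet, D: ComplexSet) -> float:
    """Per-reference best NA, averaged over the reference set."""
    if len(S) == 0:
        raise ValueError("reference set is empty")
    if len(D) == 0:
        return 0.0
    na = _na_matrix(S, D)
    return float(na.max(axis=1).mean())


def frac(S: ComplexSet, D: ComplexSet, omega: float = OMEGA_FRAC) -> float:
    """Fraction of reference complexes matched by >= 1 prediction at ``omega``."""
    if len(S) == 0:
        raise ValueError("reference set is empty")
    if len(D) == 0:
        return 0.0
    na = _na_matrix(S, D)
    return float(np.mean(na.max(axis=1) >= omega))


def _best_jaccard(c: frozenset[str], others: ComplexSet) -> float:
    best = 0.0
    for o in others:
        inter = len(c & o)
        if inter:
            best = max(best, inter / len(c | o))
    return best


def jaccard_composite(S: ComplexSet, D: ComplexSet) -> float:
    """Size-weighted best-Jaccard of each side, harmonically combined."""
    if len(S) == 0 or len(D) == 0:
        return 0.0
    jd_num = sum(len(d) * _best_jaccard(d, S) for d in D)
    jd_den = sum(len(d) for d in D)
    js_num = sum(len(s) * _best_jaccard(s, D) for s in S)
    js_den = sum(len(s) for s in S)
    jaccard_d = jd_num / jd_den
    jaccard_s = js_num / js_den
    if jaccard_d + jaccard_s == 0:
        return 0.0
    return 2 * jaccard_d * jaccard_s / (jaccard_d + jaccard_s)


@dataclass
class EvaluationReport:
    """All headline and component metric values for one (S, D) pair."""

    f_measure: float
    acc: float
    mmr: float
    frac: float
    jaccard: float
    total_score: float
    precision: float
    recall: float
    sn: float
    ppv: float
    n_reference: int
    n_predicted: int
    omega_match: float = OMEGA_MATCH
    omega_frac: float = OMEGA_FRAC

    def summary(self) -> str:
        rows = [
            ("reference complexes", self.n_reference),
            ("predicted complexes", self.n_predicted),
            ("precision", self.precision),
            ("recall", self.recall),
            ("F-measure", self.f_measure),
            ("Sn", self.sn),
            ("PPV", self.ppv),
            ("ACC", self.acc),
            ("MMR", self.mmr),
            ("Frac", self.frac),
            ("Jaccard", self.jaccard),
            ("total score", self.total_score),
        ]
        width = max(len(name) for name, _ in rows)
        lines = ["Complex detection evaluation", "-" * 40]
        for name, value in rows:
            if isinstance(value, int):
                lines.append(f"{name:<{width}}  {value}")
            else:
                lines.append(f"{name:<{width}}  {value:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "f_measure": self.f_measure,
            "acc": self.acc,
            "mmr": self.mmr,
            "frac": self.frac,
            "jaccard": self.jaccard,
            "total_score": self.total_score,
            "precision": self.precision,
            "recall": self.recall,
            "sn": self.sn,
            "ppv": self.ppv,
        }


def total_score(report: EvaluationReport) -> float:
    """Sum of the five headline metrics."""
    return report.f_measure + report.acc + report.mmr + report.frac + report.jaccard


def evaluate(
    S: ComplexSet,
    D: ComplexSet,
    omega_match: float = OMEGA_MATCH,
    omega_frac: float = OMEGA_FRAC,
) -> EvaluationReport:
    """Compute the full metric battery for reference ``S`` vs prediction ``D``."""
    if len(S) == 0:
        raise ValueError("reference set is empty")
    if len(D) == 0:
        logger.warning("empty prediction set; all metrics reported as 0")
        return EvaluationReport(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, len(S), 0,
                                omega_match, omega_frac)
    precision, recall, f = f_measure(S, D, omega=omega_match)
    sn, ppv, a = acc(S, D)
    m = mmr(S, D)
    fr = frac(S, D, omega=omega_frac)
    j = jaccard_composite(S, D)
    report = EvaluationReport(
        f_measure=f, acc=a, mmr=m, frac=fr, jaccard=j, total_score=0.0,
        precision=precision, recall=recall, sn=sn, ppv=ppv,
        n_reference=len(S), n_predicted=len(D),
        omega_match=omega_match, omega_frac=omega_frac,
    )
    report.total_score = total_score(report)
    return report


# ---------------------------------------------------------------------------
# functional enrichment
# ---------------------------------------------------------------------------

def complex_pvalue(C: Iterable[str], F: Iterable[str], V: Iterable[str]) -> float:
    """Hypergeometric upper-tail ``P(X >= k)`` for overlap ``k = |C ∩ F|``.

    ``V`` is the background protein universe. ``k = 0`` gives 1.
    """
    C, F, V = set(C), set(F), set(V)
    if len(C) > len(V):
        raise ValueError("complex larger than the background universe")
    k = len(C & F)
    if k == 0:
        return 1.0
    # survival function at k-1 == P(X >= k); scipy evaluates in log space
    return float(hypergeom.sf(k - 1, len(V), len(F & V), len(C)))


@dataclass
class EnrichmentResult:
    complex: frozenset[str]
    best_term: str | None
    p_value: float
    significant: bool


ENRICHMENT_BINS = (
    ("<1e-20", 0.0, 1e-20),
    ("[1e-20,1e-15)", 1e-20, 1e-15),
    ("[1e-15,1e-10)", 1e-15, 1e-10),
    ("[1e-10,1e-5)", 1e-10, 1e-5),
    ("[1e-5,0.01)", 1e-5, SIGNIFICANCE),
)


def enrichment_report(
    D: ComplexSet,
    groups: Mapping[str, set[str]],
    V: Iterable[str],
    alpha: float = SIGNIFICANCE,
) -> tuple[list[EnrichmentResult], dict[str, int]]:
    """Smallest p-value per complex over all functional groups, plus a binned
    summary of the significant complexes.

    The summary counts complexes whose minimum p-value falls in each decade
    bin; the bins partition ``[0, alpha)`` so their counts sum to the
    significant total (key ``"significant"``; ``"total"`` is ``|D|``).
    """
    if not groups:
        raise ValueError("no functional groups supplied")
    V = set(V)
    results: list[EnrichmentResult] = []
    for c in D:
        best_p = 1.0
        best_term: str | None = None
        for term in sorted(groups):
            p = complex_pvalue(c, groups[term], V)
            if p < best_p:
                best_p, best_term = p, term
        results.append(
            EnrichmentResult(
                complex=c, best_term=best_term, p_value=best_p,
                significant=best_p < alpha,
            )
        )
    summary = {label: 0 for label, _, _ in ENRICHMENT_BINS}
    summary["significant"] = 0
    summary["total"] = len(results)
    for r in results:
        if r.significant:
            summary["significant"] += 1
            for label, lo, hi in ENRICHMENT_BINS:
                if lo <= r.p_value < hi:
                    summary[label] += 1
                    break
    return results, summary
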