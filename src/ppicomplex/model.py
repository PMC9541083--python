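"""Model/results facade over the detection pipeline.

:class:`ComplexDetectionModel` is constructed from a weighted PPI network
plus the biological evidence bundle, in the spirit of statsmodels model
objects: the data is fixed at construction, ``fit`` runs the estimation —
here, the adaptive harmony search over (GCE, inflate, ratio) — and returns a
:class:`ComplexDetectionResults` carrying the selected parameters, the
detected complexes, the optimization trace and a ``summary()`` table.
``detect`` runs the pipeline once at fixed user parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import harmony
from .filtering import filter_complexes
from .fitness import fitness as cluster_fitness
from .forming import form_complexes
from .harmony import ParameterBounds, ScheduleConstants
from .metrics import EvaluationReport, evaluate
from .mining import detect_cores
from .ppi_io import (
    ComplexSet,
    EvidenceBundle,
    WeightedPPINetwork,
    read_evidence,
    read_network,
)
from .weighting import load_precomputed_weights, weight_network

__all__ = ["ComplexDetectionModel", "ComplexDetectionResults"]


class ComplexDetectionModel:
    """Core-attachment protein complex detector for one weighted network.

    Parameters
    ----------
    network : WeightedPPINetwork
        The (already weighted) PPI network.
    evidence : EvidenceBundle
        Expression, localization and functional annotation evidence.
    annotation_source : str
        Which annotation namespace drives the functional filter: ``"all"``
        (union, default) or a single branch ``"cc"``/``"bp"``/``"mf"``.
    bounds, consts
        Parameter search ranges and harmony-search schedule constants.
    """

    def __init__(
        self,
        network: WeightedPPINetwork,
        evidence: EvidenceBundle,
        annotation_source: str = "all",
        stop_terms: Sequence[str] = (),
        max_rounds: int = 2,
        bounds: ParameterBounds | None = None,
        consts: ScheduleConstants | None = None,
    ):
        self.network = network
        self.evidence = evidence
        if annotation_source == "all":
            self.annotations: Mapping[str, set[str]] = evidence.annotations
        elif annotation_source in ("cc", "bp", "mf"):
            self.annotations = evidence.branch_annotations.get(annotation_source, {})
        else:
            raise ValueError("annotation_source must be one of: all, cc, bp, mf")
        self.stop_terms = tuple(stop_terms)
        self.max_rounds = max_rounds
        self.bounds = bounds or ParameterBounds()
        self.consts = consts or ScheduleConstants()
        self._objective = harmony.make_objective(
            network,
            evidence,
            annotations=dict(self.annotations),
            max_rounds=max_rounds,
            stop_terms=self.stop_terms,
        )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_files(
        cls,
        network_path,
        expression_path=None,
        localization_path=None,
        annotation_path=None,
        default_weight: float = 1.0,
        weighting: str | None = None,
        precomputed_weights=None,
        **kwargs,
    ) -> "ComplexDetectionModel":
        """Build a model from the on-disk artifacts.

        ``weighting`` may name a branch-similarity scorer (e.g. ``"jaccard"``)
        to re-weight the network from annotations; ``precomputed_weights``
        loads a 3-column weight TSV instead.
        """
        net = read_network(network_path, default_weight=default_weight)
        evidence = read_evidence(expression_path, localization_path, annotation_path)
        if precomputed_weights is not None:
            net = load_precomputed_weights(net, precomputed_weights)
        elif weighting is not None:
            net = weight_network(net, evidence, scorer=weighting)
        return cls(net, evidence, **kwargs)

    # -- estimation --------------------------------------------------------
    def objective(self, gce: float, inflate: float, ratio: float) -> float:
        """OF_fitness at one parameter triple (memoized)."""
        of, _ = self._objective(gce, inflate, ratio)
        return of

    def detect(self, gce: float, inflate: float, ratio: float) -> ComplexSet:
        """Run detect → form → filter once at fixed parameters."""
        _, complexes = self._objective(gce, inflate, ratio)
        return complexes

    def fit(
        self,
        method: str = "harmony",
        seed: int = 0,
        gce: float | None = None,
        inflate: float | None = None,
        ratio: float | None = None,
        maxiter: int | None = None,
        hms: int | None = None,
    ) -> "ComplexDetectionResults":
        """Estimate the pipeline parameters and detect complexes.

        ``method="harmony"`` (default) runs the adaptive harmony search;
        ``method="fixed"`` evaluates the pipeline at the supplied
        (gce, inflate, ratio) triple.
        """
        if method == "fixed":
            if None in (gce, inflate, ratio):
                raise ValueError("method='fixed' requires gce, inflate and ratio")
            of, complexes = self._objective(gce, inflate, ratio)
            return ComplexDetectionResults(
                model=self,
                gce=gce,
                inflate=inflate,
                ratio=ratio,
                objective=of,
                complexes=complexes,
                trace=pd.DataFrame(),
                method="fixed",
                seed=seed,
            )
        if method != "harmony":
            raise ValueError("method must be 'harmony' or 'fixed'")
        consts = self.consts
        if maxiter is not None or hms is not None:
            from dataclasses import replace

            consts = replace(
                consts,
                maxiter=maxiter if maxiter is not None else consts.maxiter,
                hms=hms if hms is not None else consts.hms,
            )
        result = harmony.optimize(self._objective, seed=seed, bounds=self.bounds, consts=consts)
        best = result.best
        return ComplexDetectionResults(
            model=self,
            gce=best.gce,
            inflate=best.inflate,
            ratio=best.ratio,
            objective=float(best.objective),
            complexes=result.complexes,
            trace=result.trace,
            method="harmony",
            seed=seed,
        )


@dataclass
class ComplexDetectionResults:
    """Fitted parameters, detected complexes and diagnostics."""

    model: ComplexDetectionModel
    gce: float
    inflate: float
    ratio: float
    objective: float
    complexes: ComplexSet
    trace: pd.DataFrame
    method: str
    seed: int

    @property
    def params(self) -> dict[str, float]:
        return {"gce": self.gce, "inflate": self.inflate, "ratio": self.ratio}

    def complex_fitness(self) -> pd.DataFrame:
        """Per-complex size and fitness table."""
        rows = [
            {
                "complex": " ".join(sorted(c)),
                "size": len(c),
                "fitness": cluster_fitness(c, self.model.network),
            }
            for c in self.complexes
        ]
        return pd.DataFrame(rows, columns=["complex", "size", "fitness"])

    def evaluate(self, reference: ComplexSet, **kwargs) -> EvaluationReport:
        """Score the detected complexes against a reference catalog."""
        return evaluate(reference, self.complexes, **kwargs)

    def summary(self) -> str:
        sizes = [len(c) for c in self.complexes]
        mean_size = sum(sizes) / len(sizes) if sizes else 0.0
        lines = [
            "Protein complex detection results",
            "=" * 46,
            f"{'method':<26}{self.method}",
            f"{'seed':<26}{self.seed}",
            f"{'proteins in network':<26}{len(self.model.network)}",
            f"{'interactions':<26}{self.model.network.n_edges}",
            "-" * 46,
            f"{'GCE (co-expression thr.)':<26}{self.gce:.4f}",
            f"{'MCL inflation':<26}{self.inflate:.4f}",
            f"{'seed ratio':<26}{self.ratio:.4f}",
            f"{'objective (sum fitness)':<26}{self.objective:.4f}",
            "-" * 46,
            f"{'detected complexes':<26}{len(self.complexes)}",
            f"{'mean complex size':<26}{mean_size:.2f}",
            "=" * 46,
        ]
        return "\n".join(lines)
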