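"""Scoring of detection output against a truth table.

Matching is at the unordered-gene-pair level (the pair metric); breakpoint
distances are recorded for matched pairs and, in strict mode, also
required to be within a tolerance for a prediction to count as true
positive.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

log = logging.getLogger(__name__)


class PredictedFusion(NamedTuple):
    gene_a: str
    gene_b: str
    breakpoint_a: int
    breakpoint_b: int
    support_count: int


class TruthFusion(NamedTuple):
    gene_a: str
    gene_b: str
    breakpoint_a: int
    breakpoint_b: int


@dataclass
class EvalResult:
    n_truth: int
    n_predicted: int
    n_true_positive: int
    precision: float
    recall: float
    f1: float
    # unordered pair -> (|bp error gene a|, |bp error gene b|), canonical order
    breakpoint_errors: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict
    )
    tp_support: list[int] = field(default_factory=list)
    fp_support: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_predicted": self.n_predicted,
            "n_true_positive": self.n_true_positive,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision == 0 and recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def match_predictions(
    predicted: Sequence,
    truth: Sequence,
    breakpoint_tol: int = 25,
    strict: bool = False,
) -> EvalResult:
    """Score predictions against truth.

    ``predicted`` items need gene_a/gene_b/breakpoint_a/breakpoint_b and
    (optionally) support_count attributes; ``truth`` items need
    gene_a/gene_b/breakpoint_a/breakpoint_b.

    A prediction is a true positive iff its unordered gene pair appears in
    the truth set (each truth fusion matches at most one prediction).
    Breakpoint distances are recorded but only required to be within
    ``breakpoint_tol`` when ``strict`` is set.  Duplicate predicted pairs
    are counted once, with a warning.
    """
    truth_by_pair: dict[tuple[str, str], dict[str, int]] = {}
    for t in truth:
        pair = _canonical(t.gene_a, t.gene_b)
        truth_by_pair[pair] = {t.gene_a: t.breakpoint_a, t.gene_b: t.breakpoint_b}

    seen: set[tuple[str, str]] = set()
    matched: set[tuple[str, str]] = set()
    n_predicted = 0
    n_tp = 0
    bp_errors: dict[tuple[str, str], tuple[int, int]] = {}
    tp_support: list[int] = []
    fp_support: list[int] = []

    for p in predicted:
        pair = _canonical(p.gene_a, p.gene_b)
        if pair in seen:
            log.warning("duplicate predicted gene pair %s; counted once", pair)
            continue
        seen.add(pair)
        n_predicted += 1
        support = getattr(p, "support_count", 0)
        truth_bp = truth_by_pair.get(pair)
        is_tp = truth_bp is not None and pair not in matched
        if is_tp:
            pred_bp = {p.gene_a: p.breakpoint_a, p.gene_b: p.breakpoint_b}
            errors = tuple(abs(pred_bp[g] - truth_bp[g]) for g in pair)
            if strict and any(e > breakpoint_tol for e in errors):
                is_tp = False
            else:
                bp_errors[pair] = errors
                matched.add(pair)
        if is_tp:
            n_tp += 1
            tp_support.append(support)
        else:
            fp_support.append(support)

    n_truth = len(truth_by_pair)
    precision = n_tp / n_predicted if n_predicted else 0.0
    recall = n_tp / n_truth if n_truth else 0.0
    return EvalResult(
        n_truth=n_truth,
        n_predicted=n_predicted,
        n_true_positive=n_tp,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        breakpoint_errors=bp_errors,
        tp_support=tp_support,
        fp_support=fp_support,
    )


def read_predictions_tsv(path) -> list[PredictedFusion]:
    """Read a detection report TSV (as written by the detect command)."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PredictedFusion(
                    gene_a=row["gene_a"],
                    gene_b=row["gene_b"],
                    breakpoint_a=int(row["breakpoint_a"]),
                    breakpoint_b=int(row["breakpoint_b"]),
                    support_count=int(row["support_count"]),
                )
            )
    return out


def read_truth_tsv(path) -> list[TruthFusion]:
    """Read a simulator truth table TSV."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthFusion(
                    gene_a=row["gene_a"],
                    gene_b=row["gene_b"],
                    breakpoint_a=int(row["breakpoint_a"]),
                    breakpoint_b=int(row["breakpoint_b"]),
                )
            )
    return out


def run_simulation_study(
    n_datasets: int = 10,
    base_seed: int = 1,
    n_genes: int = 140,
    n_fusions: int = 20,
    total_reads: int = 50000,
    params=None,
    error_free: bool = False,
    strict: bool = False,
) -> list[EvalResult]:
    """Reproduce the simulation benchmark at a configurable scale:
    generate ``n_datasets`` seed-controlled datasets (fusion expression
    split half high-TPM / half low-TPM), run detection with default
    thresholds, and score each dataset against its truth table.

    Dataset i uses seed ``base_seed * 1000 + i``.  Intermediate files go
    to a temporary directory and are removed.
    """
    from tempfile import TemporaryDirectory

    from .annotation import parse_gtf
    from .fusion_core import DetectionParams, run_detection
    from .simulate import SimConfig, simulate_dataset

    if params is None:
        params = DetectionParams()
    results = []
    for i in range(n_datasets):
        config = SimConfig(
            seed=base_seed * 1000 + i,
            n_genes=n_genes,
            n_fusions=n_fusions,
            total_reads=total_reads,
            error_free=error_free,
            write_fastq=False,
        )
        with TemporaryDirectory() as tmp:
            out = simulate_dataset(config, tmp)
            annotation = parse_gtf(out.gtf)
            candidates = run_detection(out.sam, annotation, params)
            results.append(
                match_predictions(
                    candidates,
                    out.truth.fusions,
                    breakpoint_tol=params.bin_size // 2,
                    strict=strict,
                )
            )
    return results


def write_metrics(result: EvalResult, json_path=None, tsv_path=None) -> None:
    data = result.to_dict()
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            keys = list(data)
            fh.write("\t".join(keys) + "\n")
            fh.write("\t".join(str(data[k]) for k in keys) + "\n")
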