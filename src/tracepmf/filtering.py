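"""Decoy-calibrated score thresholding and low-complexity annotation.

Every hit against the reversed-sequence decoy database is assumed false.
Allowing a chosen fraction of the highest-scoring decoy unique peptides
("false-negative rate", 5% by convention here) above the cutoff fixes the
score threshold: rank the decoy unique-peptide scores, take the k-th
highest with k = floor(fn_rate * n), and accept forward peptides scoring
at or above it. A URF is flagged reliable when at least one accepted
forward peptide maps onto it.

Peptides are additionally annotated with a composition bias in bits — the
Kullback-Leibler divergence of the peptide's residue composition from the
uniform 20-letter background, equivalently log2(20) minus the Shannon
entropy of the composition. High values mean biased (low-complexity or
repetitive) sequence; the conventional flagging line is 2.5 bits. The
flag is an annotation, not an exclusion.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pmf_search import PeptideAssignment
from .report import percent

logger = logging.getLogger(__name__)

MAX_BIAS_BITS = math.log2(20)


@dataclass(frozen=True)
class ThresholdResult:
    fn_rate: float
    n_decoy_unique: int
    k_pass_decoy: int
    threshold_score: float
    n_forward_unique: int | None = None
    n_forward_pass: int | None = None
    forward_pass_fraction: float | None = None


@dataclass(frozen=True)
class ComplexityAnnotation:
    peptide_sequence: str
    bias_bits: float
    low_complexity_flag: bool


def select_decoy_threshold(
    decoy_scores: Sequence[float], fn_rate: float = 0.05
) -> ThresholdResult:
    """Score cutoff admitting floor(fn_rate * n) decoy unique peptides.

    The threshold is the k-th highest decoy score and "passing" means
    score >= threshold, so with distinct scores exactly k decoy peptides
    pass. Ties at the threshold all pass, with a logged warning about the
    excess over k. fn_rate = 0 admits nothing on either database (the
    threshold is infinite).
    """
    n = len(decoy_scores)
    if n == 0:
        raise ValueError("decoy score list is empty")
    if not 0.0 <= fn_rate <= 1.0:
        raise ValueError("fn_rate must be in [0, 1]")
    k = math.floor(fn_rate * n)
    ranked = sorted(decoy_scores, reverse=True)
    if k == 0:
        # admit nothing at all, on either database
        threshold = math.inf
        k_pass = 0
    else:
        threshold = ranked[k - 1]
        k_pass = sum(1 for s in decoy_scores if s >= threshold)
        if k_pass > k:
            logger.warning(
                "threshold ties: %d decoy peptides pass (expected %d)",
                k_pass, k,
            )
    return ThresholdResult(
        fn_rate=fn_rate,
        n_decoy_unique=n,
        k_pass_decoy=k_pass,
        threshold_score=threshold,
    )


def apply_threshold(
    forward_assignments: Sequence[PeptideAssignment],
    threshold: ThresholdResult | float,
) -> tuple[list[PeptideAssignment], ThresholdResult | None]:
    """Retain forward assignments with best_score >= threshold.

    Returns the passing assignments and, when a ThresholdResult was
    given, a copy completed with the forward counts and pass percentage.
    """
    cutoff = (
        threshold.threshold_score
        if isinstance(threshold, ThresholdResult)
        else float(threshold)
    )
    passing = [a for a in forward_assignments if a.best_score >= cutoff]
    result = None
    if isinstance(threshold, ThresholdResult):
        n_fwd = len(forward_assignments)
        result = replace(
            threshold,
            n_forward_unique=n_fwd,
            n_forward_pass=len(passing),
            forward_pass_fraction=percent(len(passing), n_fwd).value if n_fwd else None,
        )
    return passing, result


def flag_urfs(
    passing_assignments: Iterable[PeptideAssignment],
    all_searched_urfs: Iterable[str],
) -> tuple[dict[str, int], float]:
    """Reliable-URF flagging: >= 1 passing forward peptide mapped on it.

    Returns {urf_id: passing-peptide count} over the flagged URFs and the
    flagged percentage of all searched URFs.
    """
    searched = set(all_searched_urfs)
    counts: Counter[str] = Counter()
    for a in passing_assignments:
        unknown = [e for e in a.entry_ids if e not in searched]
        if unknown:
            raise ValueError(
                f"passing peptide {a.peptide_sequence!r} maps to "
                f"unsearched URF(s): {unknown[:3]}"
            )
        for entry in set(a.entry_ids):
            counts[entry] += 1
    fraction = percent(len(counts), len(searched)).value if searched else 0.0
    return dict(counts), fraction


def composition_bias_bits(
    peptide_sequence: str, threshold: float = 2.5
) -> ComplexityAnnotation:
    """Composition bias of a peptide in bits (KL from uniform background).

    bias = sum_a f_a * log2(f_a / (1/20)) over the residues present;
    0 for a peptide using all 20 residues equally, log2(20) ~ 4.32 for a
    homopolymer. Flag set iff bias > threshold.
    """
    if not peptide_sequence:
        raise ValueError("empty peptide sequence")
    n = len(peptide_sequence)
    bias = 0.0
    for count in Counter(peptide_sequence).values():
        f = count / n
        bias += f * math.log2(f * 20.0)
    bias = min(max(bias, 0.0), MAX_BIAS_BITS)
    return ComplexityAnnotation(peptide_sequence, bias, bias > threshold)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_threshold_json(result: ThresholdResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.__dict__, indent=2) + "\n")


def write_reliable_urfs_tsv(urf_counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(urf_counts.items()), columns=["urf_id", "n_passing_peptides"]
    ).to_csv(path, sep="\t", index=False)


def write_complexity_tsv(
    annotations: Iterable[ComplexityAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "peptide_sequence": a.peptide_sequence,
            "bias_bits": a.bias_bits,
            "low_complexity_flag": a.low_complexity_flag,
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["peptide_sequence", "bias_bits", "low_complexity_flag"]
    ).to_csv(path, sep="\t", index=False)
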