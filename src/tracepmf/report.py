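"""Summary statistics and overlap tables in the pipeline's reporting style.

Percentages are rendered with exactly two decimals, rounded half-up —
the convention every derived proportion in this pipeline follows (e.g.
1249 of 23,376 unique peptides -> 5.34%).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class Percent(NamedTuple):
    value: float
    text: str


def percent(numerator: int, denominator: int) -> Percent:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return Percent(float(value), f"{value}%")


def overlap_summary(
    candidate_ids: Iterable[str],
    homology_pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Per-study and union overlap of candidates with external gene sets.

    ``homology_pairs`` are (candidate_id, study_label) links from an
    external alignment tool. A candidate overlaps a study if at least one
    pair links it there; the union row counts candidates linked to any
    study. Pairs naming unknown candidates are skipped with a warning.
    """
    candidates = set(candidate_ids)
    n = len(candidates)
    per_study: dict[str, set[str]] = {}
    for cand, study in homology_pairs:
        if cand not in candidates:
            logger.warning("unknown candidate id %r in homology pairs; skipped", cand)
            continue
        per_study.setdefault(study, set()).add(cand)
    rows = []
    union: set[str] = set()
    for study in sorted(per_study):
        members = per_study[study]
        union |= members
        rows.append(
            {
                "study": study,
                "n_overlap": len(members),
                "n_candidates": n,
                "pct": percent(len(members), n).value if n else 0.0,
            }
        )
    rows.append(
        {
            "study": "any",
            "n_overlap": len(union),
            "n_candidates": n,
            "pct": percent(len(union), n).value if n else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["study", "n_overlap", "n_candidates", "pct"])


def summary_table(counts: Mapping[str, int], ratios: Sequence[tuple[str, str, str]]) -> pd.DataFrame:
    """Named counts plus derived percentages.

    ``ratios`` lists (name, numerator_key, denominator_key) triples
    resolved against ``counts``.
    """
    rows = [{"quantity": k, "value": v, "unit": "count"} for k, v in counts.items()]
    for name, num_key, den_key in ratios:
        rows.append(
            {
                "quantity": name,
                "value": percent(counts[num_key], counts[den_key]).value,
                "unit": "%",
            }
        )
    return pd.DataFrame(rows, columns=["quantity", "value", "unit"])


def render_markdown(df: pd.DataFrame, title: str) -> str:
    """Minimal GitHub-style markdown table."""
    cols = list(df.columns)
    lines = [f"# {title}", "", "| " + " | ".join(cols) + " |",
             "|" + "|".join(" --- " for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def write_report(df: pd.DataFrame, out_prefix: str | Path, title: str) -> None:
    out_prefix = Path(out_prefix)
    df.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    out_prefix.with_suffix(".md").write_text(render_markdown(df, title))


def read_homology_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV: candidate_id, study_label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["candidate", "study"],
                     comment="#")
    return list(df.itertuples(index=False, name=None))
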