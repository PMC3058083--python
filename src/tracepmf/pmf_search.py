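"""Peptide-mass-fingerprint search against theoretical digests.

Each gel spot yields a fingerprint: a list of singly-protonated (MH+)
peptide masses. Every database entry (forward or decoy) is scored against
the fingerprint by greedy one-to-one matching of experimental peaks to
theoretical tryptic masses within a mass tolerance, followed by a
binomial significance model:

    p      = min(1, m * w / R)   per-peak chance of a random match, where
                                 m = entry peptides inside the query mass
                                 range, w = full tolerance window width,
                                 R = query mass range span
    P      = P(X >= k), X ~ Binomial(n, p), k matched of n query peaks
    score  = -10 * log10(P)

This is a documented stand-in for the commercial MOWSE-based PMF scorer:
same -10*log10(P) scale, fully specified, identical code path for forward
and decoy entries. Hits are ranked (score desc, matched desc, entry id
asc) and the top N per database label are retained after partitions are
merged. Peptide assignments are then collapsed: when the same peptide
maps onto two or more URFs, the highest score is retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.stats import binom

from .digest import TheoreticalPeptide, tryptic_peptides

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keeps -10*log10(P) finite


@dataclass(frozen=True)
class SpectrumFingerprint:
    """One spot's observed MH+ peak list (sorted ascending on creation)."""

    spot_id: str
    peaks: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.peaks):
            raise ValueError(f"spot {self.spot_id!r}: non-positive peak mass")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))


@dataclass(frozen=True)
class ProteinHit:
    spot_id: str
    db_label: str
    entry_id: str
    matched: int
    n_peaks: int
    p_value: float
    score: float
    matched_peptides: tuple[str, ...] = ()

    def sort_key(self) -> tuple:
        return (-self.score, -self.matched, self.entry_id)


@dataclass(frozen=True)
class PeptideAssignment:
    peptide_sequence: str
    best_score: float
    db_label: str
    entry_ids: tuple[str, ...]


class DigestIndex:
    """Searchable theoretical digest of one database partition.

    Holds a globally mass-sorted peptide array plus per-entry sorted mass
    arrays, so candidate (peak, peptide) pairs and the per-entry in-range
    peptide count m are both O(log) lookups.
    """

    def __init__(
        self,
        entries: Sequence[tuple[str, str]],
        max_missed: int = 1,
        min_pep_len: int = 4,
        mods: Mapping[str, float] | None = None,
        monoisotopic: bool = True,
    ):
        self.entry_ids: list[str] = [eid for eid, _ in entries]
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise ValueError("duplicate entry ids in digest index")
        self.sorted_ids: list[str] = sorted(self.entry_ids)
        masses: list[float] = []
        entry_of: list[int] = []
        seqs: list[str] = []
        starts: list[int] = []
        self.entry_masses: list[np.ndarray] = []
        for ei, (eid, seq) in enumerate(entries):
            peps = tryptic_peptides(
                seq,
                max_missed,
                parent_id=eid,
                min_len=min_pep_len,
                mods=mods,
                monoisotopic=monoisotopic,
            )
            self.entry_masses.append(np.sort([p.mh_mass for p in peps]))
            for p in peps:
                masses.append(p.mh_mass)
                entry_of.append(ei)
                seqs.append(p.sequence)
                starts.append(p.start)
        order = np.argsort(masses, kind="stable")
        self.masses = np.asarray(masses)[order]
        self.entry_of = np.asarray(entry_of, dtype=np.int64)[order]
        self.pep_seqs = [seqs[i] for i in order]
        self.pep_starts = np.asarray(starts, dtype=np.int64)[order]

    def __len__(self) -> int:
        return len(self.entry_ids)


def _greedy_one_to_one(
    candidates: list[tuple[float, int, int, int]],
) -> list[tuple[int, int]]:
    """Greedy matching over (abs_err, pep_start, peak_key, pep_key) tuples.

    Smallest absolute error wins; ties broken by lower peptide start
    offset, then peak and peptide order. Each peak and each peptide is
    used at most once.
    """
    used_peaks: set[int] = set()
    used_peps: set[int] = set()
    accepted: list[tuple[int, int]] = []
    for _err, _start, peak_key, pep_key in sorted(candidates):
        if peak_key in used_peaks or pep_key in used_peps:
            continue
        used_peaks.add(peak_key)
        used_peps.add(pep_key)
        accepted.append((peak_key, pep_key))
    return accepted


def match_peaks(
    peaks: Sequence[float],
    theoretical: Sequence[TheoreticalPeptide],
    tolerance: float = 0.2,
    ppm: bool = False,
) -> list[tuple[float, TheoreticalPeptide]]:
    """One-to-one greedy nearest-mass matching of peaks to peptides."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    candidates = []
    for i, peak in enumerate(peaks):
        tol = peak * tolerance * 1e-6 if ppm else tolerance
        for j, pep in enumerate(theoretical):
            err = abs(peak - pep.mh_mass)
            if err <= tol:
                candidates.append((err, pep.start, i, j))
    accepted = _greedy_one_to_one(candidates)
    return sorted(
        ((peaks[i], theoretical[j]) for i, j in accepted), key=lambda t: t[0]
    )


def score_hit(matched: int, n_peaks: int, match_prob: float) -> tuple[float, float]:
    """Binomial upper-tail p-value and -10*log10 score for a hit."""
    if not 0 <= matched <= n_peaks:
        raise ValueError("need 0 <= matched <= n_peaks")
    if match_prob >= 1.0:
        logger.warning("match probability >= 1; hit carries no evidence")
        return 1.0, 0.0
    if match_prob <= 0.0:
        if matched > 0:
            raise ValueError("matched > 0 with zero match probability")
        return 1.0, 0.0
    if matched == 0:
        return 1.0, 0.0
    p_value = float(binom.sf(matched - 1, n_peaks, match_prob))
    p_value = min(1.0, max(p_value, _P_FLOOR))
    return p_value, -10.0 * np.log10(p_value)


def _match_window(peaks: np.ndarray, tolerance: float, ppm: bool) -> np.ndarray:
    if ppm:
        return peaks * tolerance * 1e-6
    return np.full(len(peaks), tolerance)


def rank_entries(
    fingerprint: SpectrumFingerprint,
    index: DigestIndex,
    db_label: str,
    tolerance: float = 0.2,
    ppm: bool = False,
    top_n: int | None = 50,
) -> list[ProteinHit]:
    """Score every entry of one partition against a fingerprint.

    Entries with no peak within tolerance of any of their peptides score
    exactly 0 (k = 0 gives P = 1); they are materialized only as needed
    to fill the ranking, in ascending entry-id order.
    """
    peaks = np.asarray(fingerprint.peaks)
    n = len(peaks)
    n_entries = len(index)
    if n_entries == 0:
        logger.warning("spot %s: empty database %r", fingerprint.spot_id, db_label)
        return []
    # candidate (peak, peptide) pairs within tolerance, grouped per entry
    per_entry: dict[int, list[tuple[float, int, int, int]]] = {}
    if n and len(index.masses):
        tols = _match_window(peaks, tolerance, ppm)
        los = np.searchsorted(index.masses, peaks - tols, side="left")
        his = np.searchsorted(index.masses, peaks + tols, side="right")
        for i in range(n):
            for j in range(los[i], his[i]):
                err = abs(peaks[i] - index.masses[j])
                per_entry.setdefault(int(index.entry_of[j]), []).append(
                    (err, int(index.pep_starts[j]), i, j)
                )
    # one-to-one matching and binomial scoring per candidate entry
    if n >= 2:
        span = peaks[-1] - peaks[0]
    else:
        span = 0.0
    mean_tol = float(np.mean(_match_window(peaks, tolerance, ppm))) if n else tolerance
    width = 2.0 * mean_tol
    scored: list[tuple[int, int, float, list[int]]] = []  # (ei, k, p, pep_js)
    for ei, cands in per_entry.items():
        accepted = _greedy_one_to_one(cands)
        k = len(accepted)
        lo, hi = peaks[0] - mean_tol, peaks[-1] + mean_tol
        em = index.entry_masses[ei]
        m = int(np.searchsorted(em, hi, side="right") - np.searchsorted(em, lo))
        p = min(1.0, m * width / span) if span > 0 else 1.0
        scored.append((ei, k, p, [j for _i, j in accepted]))
    ks = np.array([k for _, k, _, _ in scored], dtype=np.int64)
    ps = np.array([p for _, _, p, _ in scored])
    with np.errstate(divide="ignore"):
        pvals = np.where(ps < 1.0, binom.sf(ks - 1, n, np.minimum(ps, 1.0 - 1e-12)), 1.0)
    pvals = np.clip(pvals, _P_FLOOR, 1.0)
    scores = np.where(pvals < 1.0, -10.0 * np.log10(pvals), 0.0)
    hits = [
        ProteinHit(
            spot_id=fingerprint.spot_id,
            db_label=db_label,
            entry_id=index.entry_ids[ei],
            matched=int(k),
            n_peaks=n,
            p_value=float(pv),
            score=float(sc),
            matched_peptides=tuple(index.pep_seqs[j] for j in pep_js),
        )
        for (ei, k, _p, pep_js), pv, sc in zip(scored, pvals, scores)
    ]
    hits.sort(key=ProteinHit.sort_key)
    needed = n_entries if top_n is None else min(top_n, n_entries)
    if len(hits) < needed:
        have = {h.entry_id for h in hits}
        for eid in index.sorted_ids:
            if len(hits) >= needed:
                break
            if eid not in have:
                hits.append(
                    ProteinHit(
                        spot_id=fingerprint.spot_id,
                        db_label=db_label,
                        entry_id=eid,
                        matched=0,
                        n_peaks=n,
                        p_value=1.0,
                        score=0.0,
                    )
                )
        hits.sort(key=ProteinHit.sort_key)
    return hits[:needed] if top_n is not None else hits


def merge_hits(
    hit_lists: Iterable[Sequence[ProteinHit]], top_n: int | None = 50
) -> list[ProteinHit]:
    """Lossless merge of per-partition rankings, then top-N truncation."""
    merged = [h for hits in hit_lists for h in hits]
    merged.sort(key=ProteinHit.sort_key)
    return merged if top_n is None else merged[:top_n]


def search_spot(
    fingerprint: SpectrumFingerprint,
    databases: Mapping[str, Sequence[DigestIndex]],
    tolerance: float = 0.2,
    ppm: bool = False,
    top_n: int | None = 50,
) -> dict[str, list[ProteinHit]]:
    """Rank the top N entries of each database label for one fingerprint.

    ``databases`` maps a label ('forward'/'decoy') to its partitions;
    partition results are merged before truncation, so the total retained
    per spot is top_n x number of labels.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    return {
        label: merge_hits(
            (
                rank_entries(fingerprint, part, label, tolerance, ppm, top_n)
                for part in partitions
            ),
            top_n,
        )
        for label, partitions in databases.items()
    }


def collapse_unique_peptides(hits: Iterable[ProteinHit]) -> list[PeptideAssignment]:
    """One assignment per distinct (peptide, db_label); best score kept.

    A peptide's score is the score of the best hit that matched it;
    entry_ids lists every database entry it was matched in.
    """
    best: dict[tuple[str, str], float] = {}
    carriers: dict[tuple[str, str], set[str]] = {}
    for hit in hits:
        for pep in hit.matched_peptides:
            key = (hit.db_label, pep)
            if key not in best or hit.score > best[key]:
                best[key] = hit.score
            carriers.setdefault(key, set()).add(hit.entry_id)
    return [
        PeptideAssignment(
            peptide_sequence=pep,
            best_score=score,
            db_label=label,
            entry_ids=tuple(sorted(carriers[(label, pep)])),
        )
        for (label, pep), score in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[SpectrumFingerprint]:
    """Read fingerprints from an MGF file; peak m/z values are MH+ masses.

    PEPMASS is ignored (PMF peak lists carry no precursor); the spot id is
    the TITLE, falling back to an index-based id.
    """
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, spec in enumerate(reader):
            title = str(spec.get("params", {}).get("title", "") or f"spot_{i:04d}")
            spectra.append(SpectrumFingerprint(title, tuple(spec["m/z array"])))
    return spectra


def write_mgf(fingerprints: Iterable[SpectrumFingerprint], path: str | Path) -> None:
    """Write fingerprints as minimal MGF (one BEGIN/END IONS block per spot)."""
    blocks = []
    for fp in fingerprints:
        lines = ["BEGIN IONS", f"TITLE={fp.spot_id}"]
        lines += [f"{m:.4f} 1.0" for m in fp.peaks]
        lines.append("END IONS")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_peaks_txt(path: str | Path, spot_id: str | None = None) -> SpectrumFingerprint:
    """Read a one- or two-column (mass [intensity]) peak list."""
    path = Path(path)
    masses = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[\s,]+", line)
        masses.append(float(fields[0]))
    return SpectrumFingerprint(spot_id or path.stem, tuple(masses))


def write_hits_tsv(hits: Iterable[ProteinHit], path: str | Path) -> None:
    rows = [
        {
            "spot_id": h.spot_id,
            "db_label": h.db_label,
            "entry_id": h.entry_id,
            "matched": h.matched,
            "n_peaks": h.n_peaks,
            "p_value": h.p_value,
            "score": h.score,
            "matched_peptides": ";".join(h.matched_peptides),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "spot_id", "db_label", "entry_id", "matched", "n_peaks",
            "p_value", "score", "matched_peptides",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_assignments_tsv(
    assignments: Iterable[PeptideAssignment], path: str | Path
) -> None:
    rows = [
        {
            "peptide_sequence": a.peptide_sequence,
            "best_score": a.best_score,
            "db_label": a.db_label,
            "entry_ids": ";".join(a.entry_ids),
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows, columns=["peptide_sequence", "best_score", "db_label", "entry_ids"]
    ).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> list[PeptideAssignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideAssignment(
            peptide_sequence=str(r.peptide_sequence),
            best_score=float(r.best_score),
            db_label=str(r.db_label),
            entry_ids=tuple(str(r.entry_ids).split(";")) if r.entry_ids else (),
        )
        for r in df.itertuples()
    ]
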