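"""Six-frame ORF database construction from nucleotide shotgun traces.

Raw whole-genome shotgun reads ("traces") are translated, without prior
masking, into all six reading frames; maximal stop-free runs of at least
``min_len`` residues are kept as open reading frames (ORFs); ORFs are then
deduplicated by amino-acid sequence into URFs (unique ORFs), each identified
by a checksum digest of its sequence, and the URF set can be partitioned
into size-capped databases for downstream searching.

ORFs are stop-to-stop segments (trace ends count as boundaries); no start
codon is required, because truncated gene fragments on short reads would
otherwise be lost. Nucleotide coordinates are 0-based half-open on the
forward strand of the trace for both strands; the sign of the frame carries
the strand.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide alphabet accepted in traces (case-insensitive).
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

#: Checksum used for URF identifiers. SHA-1 of the uppercase amino-acid
#: string, rendered as a lowercase hex digest; recorded in run metadata.
DIGEST_ALGORITHM = "sha1"

FRAMES = (1, 2, 3, -1, -2, -3)

_INVALID_NT = re.compile(f"[^{''.join(sorted(IUPAC_NT))}]")


class ChecksumCollisionError(RuntimeError):
    """Two distinct amino-acid sequences produced the same digest."""


@dataclass(frozen=True)
class TraceRecord:
    """One raw shotgun read."""

    trace_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.trace_id:
            raise ValueError("trace_id must be non-empty")


@dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-free translated segment of one trace.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the
    forward strand regardless of the strand the ORF was read from;
    ``frame`` in {+1,+2,+3,-1,-2,-3} carries strand and offset.
    """

    aa_sequence: str
    trace_id: str
    frame: int
    nt_start: int
    nt_end: int

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if self.nt_end - self.nt_start != 3 * len(self.aa_sequence):
            raise ValueError("nucleotide span must equal 3 x residue count")


@dataclass
class UrfRecord:
    """A deduplicated ORF sequence with its checksum id and provenance."""

    urf_id: str
    aa_sequence: str
    provenances: list[tuple[str, int, int, int]] = field(default_factory=list)


def urf_digest(aa_sequence: str) -> str:
    """Checksum identifier for an amino-acid sequence (lowercase hex)."""
    return hashlib.sha1(aa_sequence.upper().encode("ascii")).hexdigest()


def six_frame_translate(trace: TraceRecord) -> dict[int, str]:
    """Translate a trace in all six frames with the standard genetic code.

    Returns a mapping frame -> translation ('*' marks stops). Frames
    +1/+2/+3 read the forward strand at offsets 0/1/2; -1/-2/-3 read the
    reverse complement at offsets 0/1/2. Trailing partial codons are
    dropped. Codons with ambiguity codes translate to the unique residue
    they imply when one exists (e.g. GGN -> G), otherwise to 'X'.

    Raises ``ValueError`` (with the offending position) on characters
    outside the IUPAC nucleotide alphabet.
    """
    seq = trace.sequence.upper()
    bad = _INVALID_NT.search(seq)
    if bad:
        raise ValueError(
            f"trace {trace.trace_id!r}: unrecognized nucleotide "
            f"{bad.group()!r} at position {bad.start()}"
        )
    forward = seq
    reverse = str(Seq(seq).reverse_complement())
    frames: dict[int, str] = {}
    for off in range(3):
        for sign, strand in ((1, forward), (-1, reverse)):
            sub = strand[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * (off + 1)] = str(Seq(sub).translate(table=1))
    return frames


def _orf_coordinates(
    frame: int, aa_start: int, aa_end: int, trace_len: int
) -> tuple[int, int]:
    """Map an aa slice of one frame translation to forward-strand nt coords."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    # reverse strand: position r on the reverse complement is forward
    # position trace_len - 1 - r
    return trace_len - (off + 3 * aa_end), trace_len - (off + 3 * aa_start)


def extract_orfs(
    trace: TraceRecord,
    min_len: int = 50,
    frames: dict[int, str] | None = None,
) -> list[OrfRecord]:
    """Extract ORFs (maximal stop-free runs) of length >= ``min_len``.

    'X' residues (ambiguous codons) do not break an ORF; they are handled
    downstream by dropping peptides that contain them.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if frames is None:
        frames = six_frame_translate(trace)
    trace_len = len(trace.sequence)
    orfs: list[OrfRecord] = []
    for frame in FRAMES:
        translation = frames[frame]
        for run in re.finditer(r"[^*]+", translation):
            if run.end() - run.start() < min_len:
                continue
            nt_start, nt_end = _orf_coordinates(
                frame, run.start(), run.end(), trace_len
            )
            orfs.append(
                OrfRecord(
                    aa_sequence=run.group(),
                    trace_id=trace.trace_id,
                    frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_end,
                )
            )
    return orfs


def dedup_urfs(orfs: Iterable[OrfRecord]) -> list[UrfRecord]:
    """Collapse ORFs into URFs keyed by checksum of the amino-acid sequence.

    Provenances aggregate every contributing ORF in input order. A digest
    collision between unequal sequences is fatal (checked by direct
    sequence comparison within each digest bucket).
    """
    by_digest: dict[str, UrfRecord] = {}
    for orf in orfs:
        digest = urf_digest(orf.aa_sequence)
        prov = (orf.trace_id, orf.frame, orf.nt_start, orf.nt_end)
        existing = by_digest.get(digest)
        if existing is None:
            by_digest[digest] = UrfRecord(digest, orf.aa_sequence, [prov])
        elif existing.aa_sequence != orf.aa_sequence:
            raise ChecksumCollisionError(
                f"digest {digest} maps to two different sequences: "
                f"first seen at {existing.provenances[0]}, now at {prov}"
            )
        else:
            existing.provenances.append(prov)
    return list(by_digest.values())


def split_database(urfs: Sequence[UrfRecord], max_entries: int) -> list[list[UrfRecord]]:
    """Partition the URF set into order-preserving chunks of <= max_entries.

    Mirrors the operational constraint that the search engine could not
    handle databases beyond a fixed entry count; search results over the
    partitions merge losslessly downstream.
    """
    if max_entries < 1:
        raise ValueError("max_entries must be >= 1")
    return [list(urfs[i : i + max_entries]) for i in range(0, len(urfs), max_entries)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_traces(path: str | Path) -> list[TraceRecord]:
    """Read traces from a (multi-)FASTA file."""
    return [
        TraceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_traces(traces: Iterable[TraceRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.trace_id, description="") for t in traces
    ]
    SeqIO.write(records, str(path), "fasta")


def _provenance_tokens(urf: UrfRecord) -> str:
    return " ".join(
        f"{tid}|{frame:+d}|{start}|{end}" for tid, frame, start, end in urf.provenances
    )


def write_urf_fasta(urfs: Iterable[UrfRecord], path: str | Path) -> None:
    """Write URFs as protein FASTA; header = urf_id + provenance tokens."""
    records = [
        SeqRecord(
            Seq(u.aa_sequence), id=u.urf_id, description=_provenance_tokens(u)
        )
        for u in urfs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_urf_fasta(path: str | Path) -> list[UrfRecord]:
    """Re-read a URF FASTA, reconstructing provenance from header tokens."""
    urfs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        provs = []
        for token in rec.description.split()[1:]:
            tid, frame, start, end = token.rsplit("|", 3)
            provs.append((tid, int(frame), int(start), int(end)))
        urfs.append(UrfRecord(rec.id, str(rec.seq), provs))
    return urfs


def write_provenance_table(urfs: Iterable[UrfRecord], path: str | Path) -> None:
    rows = [
        {
            "urf_id": u.urf_id,
            "trace_id": tid,
            "frame": frame,
            "nt_start": start,
            "nt_end": end,
        }
        for u in urfs
        for tid, frame, start, end in u.provenances
    ]
    pd.DataFrame(
        rows, columns=["urf_id", "trace_id", "frame", "nt_start", "nt_end"]
    ).to_csv(path, sep="\t", index=False)


def write_run_metadata(
    path: str | Path,
    *,
    min_len: int,
    n_traces: int,
    n_orfs: int,
    n_urfs: int,
    n_partitions: int,
) -> None:
    meta = {
        "digest_algorithm": DIGEST_ALGORITHM,
        "min_orf_len": min_len,
        "n_traces": n_traces,
        "n_orfs": n_orfs,
        "n_urfs": n_urfs,
        "n_partitions": n_partitions,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def build_database(
    traces: Iterable[TraceRecord],
    min_len: int = 50,
    max_entries: int | None = None,
) -> tuple[list[OrfRecord], list[UrfRecord], list[list[UrfRecord]]]:
    """Full ORF-database construction: translate, extract, dedup, split."""
    orfs: list[OrfRecord] = []
    for trace in traces:
        orfs.extend(extract_orfs(trace, min_len=min_len))
    urfs = dedup_urfs(orfs)
    partitions = split_database(urfs, max_entries) if max_entries else [urfs]
    return orfs, urfs, partitions
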