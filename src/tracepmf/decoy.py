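"""Reversed-sequence decoy database construction.

Hits against reversed copies of the target (forward) database are assumed
false, which calibrates the score threshold downstream. Reversal preserves
length and residue composition — hence protein mass — while displacing the
trypsin cleavage targets (K/R positions), so the decoy digest is a
realistic null for peptide-mass matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orfdb import UrfRecord

#: Prefix marking decoy entries; the forward urf_id is recoverable by
#: stripping it (the digest is computed on the forward sequence only).
DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class DecoyRecord:
    decoy_id: str
    aa_sequence: str
    source_id: str


def reverse_protein(seq: str) -> str:
    """Character-wise reversal of an amino-acid sequence (involution)."""
    if not seq:
        raise ValueError("cannot reverse an empty sequence")
    return seq[::-1]


def build_decoy_db(forward: Sequence[UrfRecord]) -> list[DecoyRecord]:
    """One decoy per forward URF, order preserved, ids prefixed."""
    ids = [u.urf_id for u in forward]
    if len(set(ids)) != len(ids):
        raise ValueError("forward URF ids must be unique")
    return [
        DecoyRecord(DECOY_PREFIX + u.urf_id, reverse_protein(u.aa_sequence), u.urf_id)
        for u in forward
    ]


def write_decoy_fasta(decoys: Iterable[DecoyRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(d.aa_sequence), id=d.decoy_id, description="")
        for d in decoys
    ]
    SeqIO.write(records, str(path), "fasta")
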