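"""In-silico tryptic digestion and peptide mass computation.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the
next residue is proline (the Keil rule). Peptides are emitted for every
number of internal missed cleavages from 0 up to ``max_missed``. Masses
are singly-protonated (MH+) monoisotopic by default:

    MH+ = sum(residue masses) + mass(H2O) + mass(proton) + fixed mods

Peptides containing 'X' (ambiguous codons upstream) have no defined mass
and are dropped, with a count kept for logging.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONOISOTOPIC = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
#: Average residue masses (Da), for the average-mass mode.
AVERAGE = {
    aa: _pmass.calculate_mass(parsed_sequence=[aa], average=True)
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}
WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
PROTON = _pmass.nist_mass["H+"][0][0]

#: Fixed modification preset: carbamidomethylation of cysteine (gel
#: workflows commonly alkylate cysteines before digestion).
CARBAMIDOMETHYL_C = {"C": 57.02146}

#: Keil rule: cleave after K/R unless followed by P.
_CLEAVAGE = re.compile(r"[KR](?!P)")


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    mh_mass: float
    missed_cleavages: int
    parent_id: str
    start: int  # 0-based offset in the parent protein


def peptide_mass(
    sequence: str,
    mods: Mapping[str, float] | None = None,
    monoisotopic: bool = True,
) -> float:
    """MH+ mass of a peptide in Da (fixed modifications additive)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = MONOISOTOPIC if monoisotopic else AVERAGE
    water = WATER_MONO if monoisotopic else WATER_AVG
    total = water + PROTON
    for aa in sequence:
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in {sequence!r}") from None
        if mods and aa in mods:
            total += mods[aa]
    return total


def cleavage_sites(protein: str) -> list[int]:
    """Positions after which trypsin cleaves (internal sites only)."""
    return [m.end() for m in _CLEAVAGE.finditer(protein) if m.end() < len(protein)]


def tryptic_peptides(
    protein: str,
    max_missed: int = 1,
    *,
    parent_id: str = "",
    min_len: int = 1,
    mods: Mapping[str, float] | None = None,
    monoisotopic: bool = True,
) -> list[TheoreticalPeptide]:
    """Enumerate tryptic peptides with 0..max_missed missed cleavages.

    ``min_len`` filters short peptides; the search layer uses 4 (below
    that, sub-tolerance mass collisions dominate), while 1 preserves the
    full-coverage property of a 0-missed digest.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0, *cleavage_sites(protein), len(protein)]
    peptides: list[TheoreticalPeptide] = []
    n_dropped_x = 0
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            seq = protein[bounds[i] : bounds[j]]
            if len(seq) < min_len:
                continue
            if "X" in seq:
                n_dropped_x += 1
                continue
            peptides.append(
                TheoreticalPeptide(
                    sequence=seq,
                    mh_mass=peptide_mass(seq, mods=mods, monoisotopic=monoisotopic),
                    missed_cleavages=j - i - 1,
                    parent_id=parent_id,
                    start=bounds[i],
                )
            )
    if n_dropped_x:
        logger.debug(
            "%s: dropped %d peptide(s) containing 'X'", parent_id or "<protein>",
            n_dropped_x,
        )
    return peptides


def digest_entries(
    entries: Sequence[tuple[str, str]],
    max_missed: int = 1,
    min_len: int = 4,
    mods: Mapping[str, float] | None = None,
    monoisotopic: bool = True,
) -> list[TheoreticalPeptide]:
    """Digest (entry_id, sequence) pairs into one flat peptide list."""
    out: list[TheoreticalPeptide] = []
    for entry_id, seq in entries:
        out.extend(
            tryptic_peptides(
                seq,
                max_missed,
                parent_id=entry_id,
                min_len=min_len,
                mods=mods,
                monoisotopic=monoisotopic,
            )
        )
    return out
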