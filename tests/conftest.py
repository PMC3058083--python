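"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from tracepmf import SimConfig, run_benchmark
from tracepmf.orfdb import OrfRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# independent codon lookup (plain dict, no Bio.Seq.translate involved)
_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for stop in _TABLE.stop_codons:
    CODON_TO_AA[stop] = "*"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def brute_force_orfs(trace_id: str, seq: str, min_len: int) -> set[OrfRecord]:
    """Position-by-position six-frame ORF scan, independent of orfdb.

    Walks every frame codon by codon with a plain dict codon table and
    emits maximal stop-free runs of >= min_len residues, computing
    forward-strand coordinates by direct arithmetic.
    """
    seq = seq.upper()
    L = len(seq)
    rc = seq.translate(_COMPLEMENT)[::-1]
    found: set[OrfRecord] = set()
    for sign, strand in ((1, seq), (-1, rc)):
        for off in range(3):
            n_codons = (len(strand) - off) // 3
            run: list[str] = []
            run_start = 0
            for ci in range(n_codons + 1):
                codon = strand[off + 3 * ci : off + 3 * ci + 3] if ci < n_codons else ""
                aa = CODON_TO_AA.get(codon, "X") if codon else "*"
                if aa == "*":
                    if len(run) >= min_len:
                        a, b = run_start, ci  # codon indices on this strand
                        if sign == 1:
                            nt_start, nt_end = off + 3 * a, off + 3 * b
                        else:
                            nt_start, nt_end = L - (off + 3 * b), L - (off + 3 * a)
                        found.add(
                            OrfRecord("".join(run), trace_id, sign * (off + 1),
                                      nt_start, nt_end)
                        )
                    run = []
                    run_start = ci + 1
                else:
                    run.append(aa)
    return found


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def benchmark_result():
    """One full synthetic pipeline run at the default study conditions."""
    return run_benchmark(SimConfig(), seed=17)
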