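"""Synthetic traces and PMF fingerprints with known ground truth.

The generator emulates the pipeline's two raw inputs at desk scale:

* shotgun traces — random nucleotide background at a chosen GC fraction
  (default 0.32, in the AT-rich range typical of the planarian genome)
  into which known proteins are planted: each protein is back-translated
  with uniform codon choice and inserted on a random strand, flanked by
  stop codons so the ORF extractor recovers the planted sequence exactly;

* peptide mass fingerprints — each tryptic MH+ mass of a source protein
  is observed independently with probability ``detect_prob``, perturbed
  by Gaussian mass error, and mixed with uniformly distributed noise
  peaks; pure-noise spectra model spots whose protein is absent from the
  database.

Everything is a pure function of (config, seed), so planted-protein
recovery and the decoy-estimated versus true false-pass fraction can be
benchmarked end to end without any external download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from scipy.stats import binomtest

from . import decoy as decoy_mod
from . import filtering, orfdb
from .digest import tryptic_peptides
from .pmf_search import (
    DigestIndex,
    PeptideAssignment,
    SpectrumFingerprint,
    collapse_unique_peptides,
    search_spot,
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# sense codons per amino acid, standard genetic code
_CODONS: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for codons in _CODONS.values():
    codons.sort()


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    planted_proteins: list[tuple[str, str]] = field(default_factory=list)
    #: (protein_id, trace_id, frame, nt_start) of each coding insertion;
    #: coordinates follow the ORF convention (forward strand, 0-based).
    placements: list[tuple[str, str, int, int]] = field(default_factory=list)
    spectrum_truth: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon for every residue."""
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()


def make_traces(
    n_traces: int,
    trace_len_mean: float,
    trace_len_sd: float,
    planted_proteins: Sequence[tuple[str, str]],
    gc_fraction: float,
    seed: int | np.random.Generator,
) -> tuple[list[orfdb.TraceRecord], SyntheticTruth]:
    """Random traces with one planted protein cassette per planted trace.

    The cassette is stop + back-translated CDS + stop, inserted in place
    (trace length unchanged) on a random strand at a random position.
    Raises if a protein cannot fit in its trace.
    """
    rng = np.random.default_rng(seed)
    if len(planted_proteins) > n_traces:
        raise ValueError("more planted proteins than traces")
    truth = SyntheticTruth(planted_proteins=list(planted_proteins))
    traces: list[orfdb.TraceRecord] = []
    for t in range(n_traces):
        length = max(30, int(round(rng.normal(trace_len_mean, trace_len_sd))))
        trace_id = f"trace_{t:05d}"
        seq = _random_background(rng, length, gc_fraction)
        if t < len(planted_proteins):
            protein_id, protein = planted_proteins[t]
            cassette = (
                str(rng.choice(_STOPS))
                + back_translate(protein, rng)
                + str(rng.choice(_STOPS))
            )
            if len(cassette) > length:
                raise ValueError(
                    f"protein {protein_id!r} ({len(protein)} aa) too long "
                    f"for trace of {length} nt"
                )
            strand = 1 if rng.random() < 0.5 else -1
            if strand == -1:
                cassette = str(Seq(cassette).reverse_complement())
            pos = int(rng.integers(0, length - len(cassette) + 1))
            seq = seq[:pos] + cassette + seq[pos + len(cassette):]
            cds_start = pos + 3  # first codon after the leading stop
            cds_end = cds_start + 3 * len(protein)
            if strand == 1:
                frame = (cds_start % 3) + 1
            else:
                frame = -(((length - cds_end) % 3) + 1)
            truth.placements.append((protein_id, trace_id, frame, cds_start))
        traces.append(orfdb.TraceRecord(trace_id, seq))
    return traces, truth


def make_fingerprint(
    protein: str,
    detect_prob: float = 0.7,
    mass_sd_da: float = 0.05,
    n_noise_peaks: int = 5,
    noise_mass_range: tuple[float, float] = (700.0, 3000.0),
    seed: int | np.random.Generator = 0,
    *,
    spot_id: str = "spot",
    max_missed: int = 0,
    min_pep_len: int = 4,
) -> tuple[SpectrumFingerprint, list[tuple[float, str]]]:
    """Simulate one spot's peak list from a protein's tryptic digest.

    Returns the fingerprint and the list of (observed mass, peptide)
    truths for the detected true peaks. At least one true peak is always
    present (a uniformly chosen peptide is forced in when every Bernoulli
    draw fails), so a non-noise spot never degenerates to pure noise.
    """
    if not 0 < detect_prob <= 1:
        raise ValueError("detect_prob must be in (0, 1]")
    if mass_sd_da < 0:
        raise ValueError("mass_sd_da must be >= 0")
    rng = np.random.default_rng(seed)
    peps = tryptic_peptides(protein, max_missed, min_len=min_pep_len)
    if not peps:
        raise ValueError("protein yields no valid peptides")
    detected = [p for p in peps if rng.random() < detect_prob]
    if not detected:
        detected = [peps[int(rng.integers(len(peps)))]]
    true_peaks = [
        (p.mh_mass + rng.normal(0.0, mass_sd_da), p.sequence) for p in detected
    ]
    noise = rng.uniform(*noise_mass_range, size=n_noise_peaks)
    peaks = [m for m, _ in true_peaks] + list(noise)
    return SpectrumFingerprint(spot_id, tuple(peaks)), true_peaks


def make_noise_fingerprint(
    n_peaks: int,
    noise_mass_range: tuple[float, float],
    seed: int | np.random.Generator,
    spot_id: str = "noise",
) -> SpectrumFingerprint:
    rng = np.random.default_rng(seed)
    return SpectrumFingerprint(
        spot_id, tuple(rng.uniform(*noise_mass_range, size=n_peaks))
    )


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Desk-scale study conditions for the end-to-end benchmark."""

    n_traces: int = 2000
    trace_len_mean: float = 800.0
    trace_len_sd: float = 80.0
    n_planted: int = 20
    protein_len_range: tuple[int, int] = (60, 120)
    gc_fraction: float = 0.32
    min_orf_len: int = 50
    max_entries: int = 2500  # forces a multi-partition database at this scale
    max_missed: int = 1
    min_pep_len: int = 4
    detect_prob: float = 0.7
    mass_sd_da: float = 0.05
    n_noise_peaks: int = 5
    n_noise_spectra: int = 20
    noise_spot_peaks: int = 15
    noise_mass_range: tuple[float, float] = (700.0, 3000.0)
    tolerance_da: float = 0.2
    top_n: int = 50
    fn_rate: float = 0.05


@dataclass
class BenchmarkResult:
    n_traces: int
    n_orfs: int
    n_urfs: int
    n_partitions: int
    n_spectra: int
    recovery_rank1: int
    n_planted: int
    recovery_rate: float
    threshold: filtering.ThresholdResult
    n_forward_true: int
    n_forward_false: int
    k_false_pass: int
    false_pass_fraction: float
    decoy_pass_fraction: float
    fdr_binom_pvalue: float
    n_flagged_urfs: int
    flagged_fraction: float


def run_benchmark(config: SimConfig | None = None, seed: int = 17) -> BenchmarkResult:
    """Full pipeline on synthetic data: build-db, decoy, digest, search,
    threshold, flag — measuring rank-1 recovery of planted proteins and
    the empirical false-pass fraction against the decoy estimate."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    # planted proteins and traces
    proteins = [
        (f"planted_{i:02d}", random_protein(rng, int(rng.integers(*cfg.protein_len_range))))
        for i in range(cfg.n_planted)
    ]
    traces, truth = make_traces(
        cfg.n_traces, cfg.trace_len_mean, cfg.trace_len_sd,
        proteins, cfg.gc_fraction, rng,
    )

    # forward and decoy databases
    orfs, urfs, partitions = orfdb.build_database(
        traces, min_len=cfg.min_orf_len, max_entries=cfg.max_entries
    )
    decoys = decoy_mod.build_decoy_db(urfs)
    decoy_parts = orfdb.split_database(decoys, cfg.max_entries)
    fwd_idx = [
        DigestIndex([(u.urf_id, u.aa_sequence) for u in part],
                    cfg.max_missed, cfg.min_pep_len)
        for part in partitions
    ]
    dec_idx = [
        DigestIndex([(d.decoy_id, d.aa_sequence) for d in part],
                    cfg.max_missed, cfg.min_pep_len)
        for part in decoy_parts
    ]
    databases = {"forward": fwd_idx, "decoy": dec_idx}

    # spectra: one per planted protein, plus pure-noise spots
    spectra: list[SpectrumFingerprint] = []
    for i, (pid, protein) in enumerate(proteins):
        fp, _ = make_fingerprint(
            protein, cfg.detect_prob, cfg.mass_sd_da, cfg.n_noise_peaks,
            cfg.noise_mass_range, rng, spot_id=f"spot_{i:03d}",
            min_pep_len=cfg.min_pep_len,
        )
        spectra.append(fp)
        truth.spectrum_truth.append((fp.spot_id, pid))
    for j in range(cfg.n_noise_spectra):
        fp = make_noise_fingerprint(
            cfg.noise_spot_peaks, cfg.noise_mass_range, rng,
            spot_id=f"spot_{cfg.n_planted + j:03d}",
        )
        spectra.append(fp)
        truth.spectrum_truth.append((fp.spot_id, "noise"))

    # search every spot against both databases
    source_urf = {pid: orfdb.urf_digest(seq) for pid, seq in proteins}
    all_hits = []
    rank1_ok = 0
    truth_by_spot = dict(truth.spectrum_truth)
    for fp in spectra:
        hits = search_spot(fp, databases, cfg.tolerance_da, top_n=cfg.top_n)
        all_hits.extend(hits["forward"])
        all_hits.extend(hits["decoy"])
        src = truth_by_spot[fp.spot_id]
        if src != "noise" and hits["forward"]:
            if hits["forward"][0].entry_id == source_urf[src]:
                rank1_ok += 1

    # unique-peptide collapse, decoy threshold, forward filtering
    assignments = collapse_unique_peptides(all_hits)
    fwd_assign = [a for a in assignments if a.db_label == "forward"]
    dec_assign = [a for a in assignments if a.db_label == "decoy"]
    threshold = filtering.select_decoy_threshold(
        [a.best_score for a in dec_assign], cfg.fn_rate
    )
    passing, threshold = filtering.apply_threshold(fwd_assign, threshold)

    # empirical false-pass fraction vs the decoy estimate
    true_peptides = {
        p.sequence
        for _, protein in proteins
        for p in tryptic_peptides(protein, cfg.max_missed, min_len=cfg.min_pep_len)
    }
    false_fwd = [a for a in fwd_assign if a.peptide_sequence not in true_peptides]
    false_pass = [a for a in false_fwd if a.best_score >= threshold.threshold_score]
    decoy_frac = threshold.k_pass_decoy / threshold.n_decoy_unique
    if false_fwd and 0.0 < decoy_frac < 1.0:
        pval = binomtest(
            len(false_pass), len(false_fwd), decoy_frac, alternative="two-sided"
        ).pvalue
    else:
        pval = 1.0

    flagged, flagged_frac = filtering.flag_urfs(passing, [u.urf_id for u in urfs])

    return BenchmarkResult(
        n_traces=len(traces),
        n_orfs=len(orfs),
        n_urfs=len(urfs),
        n_partitions=len(partitions),
        n_spectra=len(spectra),
        recovery_rank1=rank1_ok,
        n_planted=cfg.n_planted,
        recovery_rate=rank1_ok / cfg.n_planted if cfg.n_planted else 0.0,
        threshold=threshold,
        n_forward_true=len(fwd_assign) - len(false_fwd),
        n_forward_false=len(false_fwd),
        k_false_pass=len(false_pass),
        false_pass_fraction=len(false_pass) / len(false_fwd) if false_fwd else 0.0,
        decoy_pass_fraction=decoy_frac,
        fdr_binom_pvalue=float(pval),
        n_flagged_urfs=len(flagged),
        flagged_fraction=flagged_frac,
    )
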