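"""Synthetic proneuropeptide transcripts and stage count matrices with
known ground truth.

The generator emulates the canonical precursor architecture — an N-terminal
signal peptide, acidic spacer regions, and 1-20 repeated peptide copies
flanked by basic cleavage sites, with amidation (C-terminal Gly),
pyroglutamination (N-terminal Gln) and Cys-rich signatures — and 13-stage
read-count matrices with clustered expression profiles under Poisson count
noise. Every emitted object carries its ground truth so each pipeline stage
can be scored without external data.

Construction guarantees that keep the truth unambiguous: peptides and
spacers never contain K or R (so cleavage sites are exactly the inserted
basic runs), non-amidated peptides never end in G, and only pyroGlu
peptides start with Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import RAW, CountMatrix
from .io import NUCLEOTIDE, PROTEIN, SequenceRecord
from .orfs import CODON_TO_AA
from .processing import ALL_DIBASIC_PAIRS

# Synonymous codons per amino acid, from the standard table (stops excluded)
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        CODONS_BY_AA.setdefault(_aa, []).append(_codon)

# residues usable inside peptides/spacers: the 20 standard minus K and R
_NON_BASIC = "ACDEFGHILMNPQSTVWY"
# peptide-interior residues additionally avoid C (Cys is inserted explicitly)
_PEPTIDE_POOL = "ADEFGHILMNPSTVWY"
_SPACER_POOL = "DENQPSTAG"
_ACIDIC = "DENQP"
_CORE_POOL = "LIF"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic benchmark."""

    n_precursors: int = 200
    copies_range: tuple[int, int] = (1, 16)
    peptide_length_range: tuple[int, int] = (4, 18)
    sp_length_range: tuple[int, int] = (15, 30)
    amidation_rate: float = 0.5
    pyroglu_rate: float = 0.15
    cys_rich_rate: float = 0.1
    dibasic_pairs: tuple[str, ...] = ALL_DIBASIC_PAIRS
    spacer_length_range: tuple[int, int] = (2, 12)
    n_stages: int = 13
    n_genes: Optional[int] = None
    n_expression_clusters: int = 4
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    rfamide_fraction: float = 0.3
    expression_scale: float = 50.0
    seed: int = 1

    def __post_init__(self) -> None:
        for lo, hi in (
            self.copies_range, self.peptide_length_range,
            self.sp_length_range, self.spacer_length_range,
            self.library_size_range,
        ):
            if lo > hi or lo < 1:
                raise ValueError("intervals must be non-empty and positive")
        for p in (self.amidation_rate, self.pyroglu_rate, self.cys_rich_rate,
                  self.rfamide_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.peptide_length_range[0] < 3:
            raise ValueError("peptides shorter than 3 residues are undetectable")
        if self.sp_length_range[0] < 11:
            raise ValueError("signal peptides need >= 11 residues (MK + core6 + ASA)")
        if self.n_precursors < 1 or self.n_stages < 1:
            raise ValueError("n_precursors and n_stages must be positive")


@dataclass(frozen=True)
class PeptideTruth:
    sequence: str
    start: int  # 1-based on the precursor, processed span (no signature Gly)
    end: int
    amidated: bool
    pyroglutaminated: bool
    cys_count: int


@dataclass(frozen=True)
class PrecursorTruth:
    identifier: str
    protein: str
    sp_end: int
    peptides: tuple[PeptideTruth, ...]
    site_spans: tuple[tuple[int, int], ...]
    repetitive: bool
    family: str


@dataclass(frozen=True)
class ExpressionTruth:
    gene_ids: tuple[str, ...]
    cluster_labels: tuple[int, ...]
    stage_means: np.ndarray  # noiseless per-gene per-stage mean rpm


@dataclass
class GroundTruth:
    precursors: list[PrecursorTruth] = field(default_factory=list)
    expression: Optional[ExpressionTruth] = None


def _choice(rng: np.random.Generator, pool: str) -> str:
    return pool[int(rng.integers(len(pool)))]


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(pool[i] for i in rng.integers(len(pool), size=n))


def _make_signal_peptide(rng: np.random.Generator, length: int) -> str:
    """SP recoverable by the built-in heuristic: M K, hydrophobic core of
    L/I/F, then the A-S-A cleavage cassette (-3 = A, -1 = A)."""
    core = _draw(rng, _CORE_POOL, length - 5)
    return "M" + "K" + core + "ASA"


def _make_peptide(
    rng: np.random.Generator, config: GeneratorConfig, family: str
) -> tuple[str, bool, bool, int]:
    """Returns (sequence, amidated, pyroglu, cys_count); sequence is the
    processed form (no signature Gly appended yet)."""
    lo, hi = config.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    amidated = bool(rng.random() < config.amidation_rate)
    pyro = bool(rng.random() < config.pyroglu_rate)
    body = list(_draw(rng, _PEPTIDE_POOL, length))
    if family == "RFamide":
        amidated = True
        pyro = False
        body[-2:] = ["R", "F"]
    body[0] = "Q" if pyro else (
        _choice(rng, _PEPTIDE_POOL.replace("Q", "")) if body[0] == "Q" else body[0]
    )
    if not amidated and body[-1] == "G":
        body[-1] = _choice(rng, "ADEFS")
    cys = 0
    if rng.random() < config.cys_rich_rate and length >= 6:
        # a Cys pair in the interior, the classic disulfide-loop signature
        i, j = 2, length - 3
        body[i], body[j] = "C", "C"
    seq = "".join(body)
    return seq, amidated, pyro, seq.count("C")


def _spacer(rng: np.random.Generator, config: GeneratorConfig) -> str:
    lo, hi = config.spacer_length_range
    length = int(rng.integers(lo, hi + 1))
    s = _choice(rng, _ACIDIC) + _draw(rng, _SPACER_POOL, max(0, length - 1))
    # a trailing G would mimic an amidation signature on the spacer
    if s.endswith("G"):
        s = s[:-1] + "E"
    return s


def generate_precursor_set(
    config: GeneratorConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], GroundTruth]:
    """Generate transcripts, their encoded precursor proteins, and truth.

    Each protein is SP + spacer + basic run + (peptide [+G] + basic run)*,
    ending in a short acidic tail. Transcripts are reverse-translations
    with an ATG start and a stop codon and no internal stops. Fully
    deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    truth = GroundTruth()
    for idx in range(config.n_precursors):
        ident = f"pnp{idx + 1:04d}"
        family = "RFamide" if rng.random() < config.rfamide_fraction else "unassigned"
        sp_len = int(rng.integers(config.sp_length_range[0], config.sp_length_range[1] + 1))
        sp = _make_signal_peptide(rng, sp_len)
        n_copies = int(rng.integers(config.copies_range[0], config.copies_range[1] + 1))

        parts: list[str] = [sp, _spacer(rng, config)]
        pos = sum(len(p) for p in parts)
        site_spans: list[tuple[int, int]] = []
        peptides: list[PeptideTruth] = []

        def add_basic_run() -> None:
            nonlocal pos
            pair = config.dibasic_pairs[int(rng.integers(len(config.dibasic_pairs)))]
            parts.append(pair)
            site_spans.append((pos + 1, pos + 2))
            pos += 2

        add_basic_run()
        for copy_idx in range(n_copies):
            seq, amidated, pyro, cys = _make_peptide(rng, config, family)
            if copy_idx == 0 and n_copies >= 2:
                # repeat families are overwhelmingly amidated; forcing the
                # first copy also guarantees structural evidence for every
                # multi-copy precursor regardless of the repeat-scan outcome
                amidated = True
            start = pos + 1
            parts.append(seq)
            pos += len(seq)
            peptides.append(
                PeptideTruth(seq, start, pos, amidated, pyro, cys)
            )
            if amidated:
                parts.append("G")
                pos += 1
            add_basic_run()
        tail = _choice(rng, _ACIDIC) + _choice(rng, "DE")
        parts.append(tail)
        pos += len(tail)

        protein = "".join(parts)
        repetitive = n_copies >= 2
        truth.precursors.append(
            PrecursorTruth(
                ident, protein, sp_len, tuple(peptides),
                tuple(site_spans), repetitive, family,
            )
        )
        proteins.append(SequenceRecord(ident, protein, PROTEIN, "synthetic precursor"))
        nt = reverse_translate(protein, int(rng.integers(2**31 - 1)))
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        transcripts.append(
            SequenceRecord(ident, nt + stop, NUCLEOTIDE, "synthetic transcript")
        )
    return transcripts, proteins, truth


def reverse_translate(protein: str, seed: int) -> str:
    """Map each residue to a uniformly sampled synonymous codon.

    ``translate_frame(result, +1)`` returns the input; internal stops are
    impossible by construction.
    """
    rng = np.random.default_rng(seed)
    out = []
    for aa in protein:
        if aa == "*":
            raise ValueError("protein must not contain stop symbols")
        codons = CODONS_BY_AA[aa]
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


def generate_expression_matrix(
    config: GeneratorConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Generate a raw 13-stage count matrix with clustered profiles.

    Genes are partitioned into ``n_expression_clusters``; each cluster has a
    smooth single-bump stage-mean profile (in rpm units) centred on a
    cluster-specific stage. Counts are Poisson around mean x library size /
    1e6; library sizes are sampled within ``library_size_range``.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed + 20_000_000)
    n_genes = config.n_genes if config.n_genes is not None else config.n_precursors
    n_stages = config.n_stages
    k = config.n_expression_clusters
    stages = [f"stage{s + 1:02d}" for s in range(n_stages)]
    gene_ids = tuple(f"pnp{g + 1:04d}" for g in range(n_genes))

    centers = np.linspace(0, n_stages - 1, k + 2)[1:-1]
    width = max(1.0, n_stages / (2.5 * k))
    labels = tuple(int(g % k) for g in range(n_genes))
    t = np.arange(n_stages)
    means = np.zeros((n_genes, n_stages))
    for g, lab in enumerate(labels):
        bump = np.exp(-0.5 * ((t - centers[lab]) / width) ** 2)
        scale = config.expression_scale * float(rng.uniform(0.5, 2.0))
        means[g] = scale * bump + 0.05  # small floor keeps rows non-zero

    libs = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, size=n_stages
    ).astype(float)
    lam = means * libs[None, :] / 1e6
    counts = rng.poisson(lam).astype(float)

    data = pd.DataFrame(counts, index=list(gene_ids), columns=stages)
    matrix = CountMatrix(
        data=data,
        library_sizes=pd.Series(libs, index=stages),
        lengths=pd.Series(
            rng.integers(300, 3000, size=n_genes).astype(float), index=list(gene_ids)
        ),
        normalization=RAW,
    )
    truth = GroundTruth(
        expression=ExpressionTruth(gene_ids, labels, means)
    )
    return matrix, truth
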