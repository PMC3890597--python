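"""Precursor processing: cleavage sites, mature peptides, repeat motifs,
logos, MS evidence and prohormone qualification.

A proneuropeptide is processed by prohormone convertases at basic cleavage
sites (K/R). Maximal runs of basic residues are treated as single cleavage
events; the substrings between the signal peptide, the basic runs and the
C-terminus are candidate peptides. A glycine directly abutting a basic run
is the amidation signature (removed, peptide flagged amidated); an
N-terminal glutamine flags pyroglutamination (retained in the sequence).
The discovery heuristic scans for repetitions of the motif x(3-10)-K[K/R].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import AnnotationRow, SequenceRecord
from .orfs import SignalPeptideAnnotation

BASIC = frozenset("KR")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

ALL_DIBASIC_PAIRS = ("KR", "RR", "KK", "RK")


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable rules of the processing step.

    ``monobasic_enabled`` controls whether single K/R residues are reported
    as cleavage sites; ``cleave_monobasic`` controls whether liberation
    actually splits at them (off by default — prohormone convertases use
    monobasic sites only selectively, and splitting at every lone K/R would
    shred peptides such as the RFamides that carry an internal Arg).
    """

    dibasic_pairs: tuple[str, ...] = ALL_DIBASIC_PAIRS
    monobasic_enabled: bool = True
    cleave_monobasic: bool = False
    min_peptide_length: int = 3
    repeat_spacer_min: int = 3
    repeat_spacer_max: int = 10
    repeat_min_copies: int = 2
    cys_rich_min: int = 2

    def __post_init__(self) -> None:
        if self.repeat_spacer_min > self.repeat_spacer_max:
            raise ValueError("repeat_spacer_min must be <= repeat_spacer_max")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        for pair in self.dibasic_pairs:
            if pair not in ALL_DIBASIC_PAIRS:
                raise ValueError(f"invalid dibasic pair {pair!r}")


@dataclass(frozen=True)
class CleavageSite:
    """A maximal run of basic residues, 1-based inclusive span."""

    start: int
    end: int
    kind: str  # monobasic | dibasic | multibasic

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cleavage site span inverted")
        if self.kind not in ("monobasic", "dibasic", "multibasic"):
            raise ValueError(f"unknown cleavage kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MaturePeptide:
    """A predicted bioactive peptide liberated from a precursor.

    ``start``/``end`` span the processed sequence on the full precursor
    (1-based inclusive, modification glycine excluded); ``post_sp_start`` /
    ``post_sp_end`` give the same span in post-SP coordinates.
    """

    precursor_id: str
    start: int
    end: int
    sequence: str
    amidated: bool = False
    pyroglutaminated: bool = False
    cys_count: int = 0
    ms_evidence: str = "none"  # none | partial | full
    post_sp_start: int = 0
    post_sp_end: int = 0
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ms_evidence not in ("none", "partial", "full"):
            raise ValueError(f"unknown ms_evidence {self.ms_evidence!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("peptide span does not match sequence length")
        if self.pyroglutaminated and not self.sequence.startswith("Q"):
            raise ValueError("pyroglutaminated peptide must start with Q")


@dataclass
class PrecursorAnnotation:
    """One protein with its processing annotation and qualification verdict."""

    protein: SequenceRecord
    sp: Optional[SignalPeptideAnnotation] = None
    sites: list[CleavageSite] = field(default_factory=list)
    peptides: list[MaturePeptide] = field(default_factory=list)
    repetitive: bool = False
    repeat_matches: list[tuple[int, int]] = field(default_factory=list)
    evidence: set[str] = field(default_factory=set)
    qualified: bool = False
    rejection_reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """C-terminally anchored position frequency matrix.

    ``columns[k]`` is the frequency vector (over the 20 amino acids) of
    column -(k+1), i.e. ``columns[0]`` describes the last residue. The
    support of a column is the number of peptides long enough to reach it.
    """

    columns: tuple  # tuple of np.ndarray, length-20 each
    support: tuple[int, ...]

    def __post_init__(self) -> None:
        for k, col in enumerate(self.columns):
            if self.support[k] > 0 and abs(float(np.sum(col)) - 1.0) > 1e-9:
                raise ValueError(f"PFM column -{k + 1} does not sum to 1")

    def frequency(self, offset: int, residue: str) -> float:
        """Frequency of ``residue`` at C-terminal offset -1, -2, ..."""
        return float(self.columns[-offset - 1][AA_INDEX[residue]])


def detect_cleavage_sites(protein: str, config: ProcessingConfig) -> list[CleavageSite]:
    """Report maximal K/R runs as cleavage sites, sorted by start.

    Length-1 runs are monobasic (reported only when enabled), length-2 runs
    dibasic (reported only when the ordered pair is configured), length >= 3
    multibasic (always reported).
    """
    sites: list[CleavageSite] = []
    i = 0
    n = len(protein)
    while i < n:
        if protein[i] in BASIC:
            j = i
            while j < n and protein[j] in BASIC:
                j += 1
            run_len = j - i
            if run_len == 1:
                if config.monobasic_enabled:
                    sites.append(CleavageSite(i + 1, j, "monobasic"))
            elif run_len == 2:
                if protein[i:j] in config.dibasic_pairs:
                    sites.append(CleavageSite(i + 1, j, "dibasic"))
            else:
                sites.append(CleavageSite(i + 1, j, "multibasic"))
            i = j
        else:
            i += 1
    return sites


def liberate_peptides(
    protein: SequenceRecord,
    sp: Optional[SignalPeptideAnnotation],
    sites: Sequence[CleavageSite],
    config: ProcessingConfig,
) -> list[MaturePeptide]:
    """Cut the precursor into mature peptides with modification calls.

    Candidate segments are the substrings strictly between the SP end (or
    position 1), the basic-run spans used for cleavage, and the C-terminus.
    Within a segment, a trailing G immediately preceding a basic run is
    removed and flags amidation; a leading Q flags pyroglutamination (Q is
    retained so the sequence stays matchable against MS lists). Segments
    shorter than ``min_peptide_length`` after processing are dropped.
    Monobasic sites act as boundaries only when ``cleave_monobasic`` is set;
    peptides flanked by a monobasic boundary carry a provenance note.
    """
    seq = protein.sequence
    n = len(seq)
    ordered = sorted(sites, key=lambda s: s.start)
    last_end = 0
    for s in ordered:
        if s.start <= last_end or s.end > n:
            raise ValueError(
                f"cleavage site {s.start}-{s.end} overlaps a previous site or "
                f"exceeds the precursor (length {n})"
            )
        last_end = s.end
    cut_sites = [
        s for s in ordered if s.kind != "monobasic" or config.cleave_monobasic
    ]

    sp_end = sp.sp_end if sp is not None else 0
    boundaries: list[tuple[int, int, Optional[CleavageSite], Optional[CleavageSite]]] = []
    prev_end = sp_end  # 0-based end of the previous boundary region
    prev_site: Optional[CleavageSite] = None
    for s in cut_sites:
        if s.end <= sp_end:
            prev_site = s
            continue
        seg_start = max(prev_end, sp_end) + 1  # 1-based
        seg_end = s.start - 1
        boundaries.append((seg_start, seg_end, prev_site, s))
        prev_end = s.end
        prev_site = s
    boundaries.append((max(prev_end, sp_end) + 1, n, prev_site, None))

    peptides: list[MaturePeptide] = []
    for seg_start, seg_end, left, right in boundaries:
        if seg_start > seg_end:
            continue
        segment = seq[seg_start - 1 : seg_end]
        amidated = False
        end = seg_end
        if right is not None and segment.endswith("G"):
            amidated = True
            segment = segment[:-1]
            end -= 1
        if not segment or len(segment) < config.min_peptide_length:
            continue
        pyro = segment.startswith("Q")
        notes = []
        if (left is not None and left.kind == "monobasic") or (
            right is not None and right.kind == "monobasic"
        ):
            notes.append("monobasic")
        peptides.append(
            MaturePeptide(
                precursor_id=protein.identifier,
                start=seg_start,
                end=end,
                sequence=segment,
                amidated=amidated,
                pyroglutaminated=pyro,
                cys_count=segment.count("C"),
                post_sp_start=seg_start - sp_end,
                post_sp_end=end - sp_end,
                notes=tuple(notes),
            )
        )
    return peptides


def scan_repeat_motif(
    protein: str, config: ProcessingConfig
) -> tuple[list[tuple[int, int]], bool]:
    """Scan for the discovery motif x(3-10)-K[K/R].

    A match is a maximal K/R-free run whose length lies in the configured
    spacer window, immediately followed by K then K or R. Matches are taken
    left to right without overlap; the returned spans (1-based inclusive)
    cover the spacer plus the two basic residues. ``repetitive`` is true
    when at least ``repeat_min_copies`` matches are found.
    """
    lo, hi = config.repeat_spacer_min, config.repeat_spacer_max
    matches: list[tuple[int, int]] = []
    n = len(protein)
    i = 0
    consumed = 0  # 1-based position up to which the string is consumed
    while i < n:
        if protein[i] not in BASIC:
            j = i
            while j < n and protein[j] not in BASIC:
                j += 1
            run_start, run_len = i + 1, j - i  # 1-based
            if (
                run_start > consumed
                and lo <= run_len <= hi
                and j + 1 < n
                and protein[j] == "K"
                and protein[j + 1] in BASIC
            ):
                matches.append((run_start, j + 2))
                consumed = j + 2
            i = j
        else:
            i += 1
    return matches, len(matches) >= config.repeat_min_copies


def build_pfm(peptides: Sequence[str]) -> PositionFrequencyMatrix:
    """Build a C-terminally anchored position frequency matrix.

    Peptides are right-justified (no internal gaps, no pseudocounts);
    column -k is computed over the peptides of length >= k.
    """
    if len(peptides) < 2:
        raise ValueError("a PFM needs at least 2 peptides")
    for p in peptides:
        for c in p:
            if c not in AA_INDEX:
                raise ValueError(f"non-standard residue {c!r} in peptide {p!r}")
    depth = max(len(p) for p in peptides)
    columns = []
    support = []
    for k in range(1, depth + 1):
        contributing = [p for p in peptides if len(p) >= k]
        vec = np.zeros(20)
        for p in contributing:
            vec[AA_INDEX[p[-k]]] += 1
        if contributing:
            vec /= len(contributing)
        columns.append(vec)
        support.append(len(contributing))
    return PositionFrequencyMatrix(tuple(columns), tuple(support))


def match_ms_evidence(
    peptides: Sequence[MaturePeptide], observed: Sequence[AnnotationRow]
) -> list[MaturePeptide]:
    """Annotate predicted peptides with mass-spectrometry evidence.

    ``full``: an observed sequence equals the predicted sequence and the
    observed amidation/pyroGlu flags do not contradict the prediction.
    ``partial``: an observed sequence of length >= 5 is a substring of the
    predicted sequence. Inputs are untouched; copies are returned.
    """
    out: list[MaturePeptide] = []
    for pep in peptides:
        level = "none"
        for row in observed:
            obs_seq = str(row.columns[0])
            obs_ami = bool(row.columns[1])
            obs_pyro = bool(row.columns[2])
            if obs_seq == pep.sequence and not (
                (obs_ami and not pep.amidated)
                or (obs_pyro and not pep.pyroglutaminated)
            ):
                level = "full"
                break
            if len(obs_seq) >= 5 and obs_seq in pep.sequence:
                level = "partial"
        out.append(dataclasses.replace(pep, ms_evidence=level))
    return out


def qualify_precursor(
    annotation: PrecursorAnnotation,
    domain_hits: Sequence[AnnotationRow] = (),
    config: ProcessingConfig = ProcessingConfig(),
) -> PrecursorAnnotation:
    """Apply the bona-fide prohormone rule.

    A precursor qualifies when it has a signal peptide, at least one basic
    cleavage site, no conflicting (non-neuropeptide) protein domain, and at
    least one piece of evidence. Structural evidence is granted
    automatically for a repetitive architecture, amidated or
    pyroglutaminated peptides, or Cys-rich peptides.
    """
    ann = annotation
    structural = ann.repetitive or any(
        p.amidated or p.pyroglutaminated or p.cys_count >= config.cys_rich_min
        for p in ann.peptides
    )
    evidence = set(ann.evidence)
    if structural:
        evidence.add("structural")

    reasons: list[str] = []
    if ann.sp is None:
        reasons.append("no signal peptide")
    if not ann.sites:
        reasons.append("no cleavage site")
    conflicting = [
        h for h in domain_hits if h.subject_id == ann.protein.identifier
    ]
    if conflicting:
        names = ",".join(sorted({str(h.columns[1]) for h in conflicting}))
        reasons.append(f"conflicting protein domain ({names})")
    if not evidence:
        reasons.append("no supporting evidence")

    ann.evidence = evidence
    ann.rejection_reasons = reasons
    ann.qualified = not reasons
    return ann


def annotate_precursor(
    protein: SequenceRecord,
    sp: Optional[SignalPeptideAnnotation],
    config: ProcessingConfig = ProcessingConfig(),
    observed_ms: Sequence[AnnotationRow] = (),
    domain_hits: Sequence[AnnotationRow] = (),
    external_evidence: Iterable[str] = (),
) -> PrecursorAnnotation:
    """Run the full processing chain on one (post-translation) precursor."""
    sites = detect_cleavage_sites(protein.sequence, config)
    peptides = liberate_peptides(protein, sp, sites, config)
    if observed_ms:
        peptides = match_ms_evidence(peptides, observed_ms)
    matches, repetitive = scan_repeat_motif(protein.sequence, config)
    ann = PrecursorAnnotation(
        protein=protein,
        sp=sp,
        sites=sites,
        peptides=peptides,
        repetitive=repetitive,
        repeat_matches=matches,
        evidence=set(external_evidence),
    )
    if any(p.ms_evidence != "none" for p in peptides):
        ann.evidence.add("ms")
    return qualify_precursor(ann, domain_hits, config)
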