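"""Predicted proteome and secretome derivation.

Transcripts are scanned in all six reading frames for the longest open
reading frame (ATG-initiated preferred, with an open-ended fallback because
EST-derived transcripts are frequently 5'-truncated). Proteins passing the
length cutoff form the predicted proteome; those with a signal peptide (SP)
form the secretome after in-silico SP removal. SP calls can be imported from
an external predictor or made by a built-in hydropathy heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import NUCLEOTIDE, PROTEIN, SequenceRecord

FRAMES = (1, 2, 3, -1, -2, -3)

_standard = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:  # TAA, TAG, TGA
    CODON_TO_AA[_stop] = "*"

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

# Residues counted as part of a hydrophobic core run (KD >= 1.8)
_CORE_RESIDUES = frozenset("ACFILMV")
# Small/neutral residues accepted at the -1 and -3 positions of an SP cleavage site
_CLEAVAGE_RESIDUES = frozenset("AGSCTV")

SP_SEARCH_WINDOW = 45
SP_MIN_END = 5
CORE_MIN_LEN = 6
CORE_MIN_HYDROPATHY = 1.6


@dataclass(frozen=True)
class OpenReadingFrame:
    """One ORF located on the forward strand of a transcript."""

    transcript_id: str
    frame: int
    nt_start: int  # 1-based inclusive, forward strand
    nt_end: int
    protein: str
    initiator: str  # "ATG" or "open_end"

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start + 1) % 3 != 0:
            raise ValueError("ORF nucleotide span must be a whole number of codons")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain internal stops")


@dataclass(frozen=True)
class SignalPeptideAnnotation:
    """A signal-peptide call: the SP spans residues 1..sp_end."""

    protein_id: str
    sp_end: int
    score: float
    source: str  # "imported" or "heuristic"

    def __post_init__(self) -> None:
        if not (SP_MIN_END <= self.sp_end <= SP_SEARCH_WINDOW):
            raise ValueError(
                f"sp_end {self.sp_end} outside the allowed range "
                f"[{SP_MIN_END}, {SP_SEARCH_WINDOW}]"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("SP score must lie in [0, 1]")
        if self.source not in ("imported", "heuristic"):
            raise ValueError(f"unknown SP source {self.source!r}")


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def translate_frame(nt: str, frame: int) -> str:
    """Translate one reading frame with the standard genetic code.

    Negative frames read the reverse complement. Trailing partial codons are
    dropped; stops render ``*``; any codon containing N renders X.
    """
    if abs(frame) not in (1, 2, 3):
        raise ValueError(f"frame must be in +-1..3, got {frame}")
    if not nt:
        return ""
    seq = nt.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    seq = seq[abs(frame) - 1 :]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _frame_to_forward_span(frame: int, aa_start: int, aa_end: int, length: int) -> tuple[int, int]:
    """Map a codon range (0-based, end exclusive) of a frame translation to a
    1-based inclusive forward-strand nucleotide span."""
    offset = abs(frame) - 1
    lo = offset + 3 * aa_start + 1
    hi = offset + 3 * aa_end
    if frame > 0:
        return lo, hi
    # positions were on the reverse complement; mirror them
    return length - hi + 1, length - lo + 1


def find_longest_orf(
    transcript: SequenceRecord, min_protein_length: int = 120
) -> Optional[OpenReadingFrame]:
    """Return the longest ORF across all six frames, or None.

    ATG-initiated ORFs (ATG to stop, or to the frame end) are preferred; if
    none reaches ``min_protein_length``, the longest stop-free translated
    stretch is returned instead when it reaches the cutoff. Ties resolve by
    frame order +1,+2,+3,-1,-2,-3 then by smallest nt_start.
    """
    if transcript.alphabet != NUCLEOTIDE:
        raise ValueError("find_longest_orf expects a nucleotide record")
    if min_protein_length < 1:
        raise ValueError("min_protein_length must be >= 1")
    nt = transcript.sequence
    length = len(nt)
    if length < 3:
        return None

    atg_candidates: list[tuple[int, int, OpenReadingFrame]] = []
    open_candidates: list[tuple[int, int, OpenReadingFrame]] = []

    for order, frame in enumerate(FRAMES):
        aa = translate_frame(nt, frame)
        # split into stop-free stretches, tracking codon offsets
        start = 0
        n = len(aa)
        while start <= n:
            stop_idx = aa.find("*", start)
            stretch_end = stop_idx if stop_idx != -1 else n
            stretch = aa[start:stretch_end]
            if stretch:
                has_stop = stop_idx != -1
                # open-ended candidate: the full stretch
                span = _frame_to_forward_span(
                    frame, start, stretch_end + (1 if has_stop else 0), length
                )
                open_candidates.append(
                    (
                        len(stretch),
                        order,
                        OpenReadingFrame(
                            transcript.identifier, frame, span[0], span[1],
                            stretch, "open_end",
                        ),
                    )
                )
                m_idx = stretch.find("M")
                if m_idx != -1:
                    prot = stretch[m_idx:]
                    span = _frame_to_forward_span(
                        frame,
                        start + m_idx,
                        stretch_end + (1 if has_stop else 0),
                        length,
                    )
                    atg_candidates.append(
                        (
                            len(prot),
                            order,
                            OpenReadingFrame(
                                transcript.identifier, frame, span[0], span[1],
                                prot, "ATG",
                            ),
                        )
                    )
            if stop_idx == -1:
                break
            start = stop_idx + 1

    def best(cands):
        viable = [c for c in cands if c[0] >= min_protein_length]
        if not viable:
            return None
        return min(viable, key=lambda c: (-c[0], c[1], c[2].nt_start))[2]

    return best(atg_candidates) or best(open_candidates)


def predict_signal_peptide(
    protein: SequenceRecord, imported: Optional[SignalPeptideAnnotation] = None
) -> Optional[SignalPeptideAnnotation]:
    """Call a signal peptide on a protein record.

    If an imported call is supplied it is returned verbatim (source kept as
    ``imported``). Otherwise a hydropathy heuristic applies within residues
    1-45: the first maximal run of >= 6 consecutive residues from the
    Kyte-Doolittle >= 1.8 set {A,C,F,I,L,M,V} with mean hydropathy > 1.6 is
    the hydrophobic core; the net charge of residues 1-5 must be >= 0; the
    cleavage position is the first position after the core where the
    residues at -1 and -3 are small/neutral ({A,G,S,C,T,V}).
    """
    if protein.alphabet != PROTEIN:
        raise ValueError("predict_signal_peptide expects a protein record")
    if imported is not None:
        if imported.sp_end >= len(protein.sequence):
            raise ValueError("imported sp_end must be < protein length")
        return SignalPeptideAnnotation(
            protein.identifier, imported.sp_end, imported.score, "imported"
        )

    seq = protein.sequence
    window = seq[:SP_SEARCH_WINDOW]

    # net charge over residues 1-5
    charge = sum(
        1 if c in "KR" else -1 if c in "DE" else 0 for c in seq[:5]
    )
    if charge < 0:
        return None

    # first maximal run of core residues with sufficient length and hydropathy
    core: Optional[tuple[int, int]] = None  # 0-based [start, end)
    i = 0
    while i < len(window):
        if window[i] in _CORE_RESIDUES:
            j = i
            while j < len(window) and window[j] in _CORE_RESIDUES:
                j += 1
            if j - i >= CORE_MIN_LEN:
                mean_kd = sum(KYTE_DOOLITTLE[c] for c in window[i:j]) / (j - i)
                if mean_kd > CORE_MIN_HYDROPATHY:
                    core = (i, j)
                    break
            i = j
        else:
            i += 1
    if core is None:
        return None
    core_start, core_end = core
    core_mean = sum(KYTE_DOOLITTLE[c] for c in window[core_start:core_end]) / (
        core_end - core_start
    )

    # cleavage site: first position p (1-based) after the core where the
    # residues at -1 (p) and -3 (p-2) are small/neutral
    max_end = min(SP_SEARCH_WINDOW, len(seq) - 1)
    for p in range(max(core_end + 1, SP_MIN_END, 3), max_end + 1):
        if seq[p - 1] in _CLEAVAGE_RESIDUES and seq[p - 3] in _CLEAVAGE_RESIDUES:
            score = min(1.0, max(0.0, (core_mean - CORE_MIN_HYDROPATHY) / 2.9))
            return SignalPeptideAnnotation(protein.identifier, p, score, "heuristic")
    return None


def make_secretome_record(
    protein: SequenceRecord, sp: SignalPeptideAnnotation
) -> SequenceRecord:
    """Remove the SP in silico, preserving the identifier."""
    if sp.protein_id != protein.identifier:
        raise ValueError(
            f"SP call for {sp.protein_id!r} does not belong to {protein.identifier!r}"
        )
    if sp.sp_end >= len(protein.sequence):
        raise ValueError("sp_end must be strictly inside the protein")
    mature = protein.sequence[sp.sp_end :]
    return SequenceRecord(
        protein.identifier, mature, PROTEIN,
        f"signal peptide (1-{sp.sp_end}) removed",
    )
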