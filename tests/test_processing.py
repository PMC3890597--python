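"""Cleavage sites, peptide liberation, repeat scanning, logos, MS evidence
and prohormone qualification."""

import random
import re

import numpy as np
import pytest

from pnpkit.io import PROTEIN, AnnotationRow, SequenceRecord
from pnpkit.orfs import SignalPeptideAnnotation, predict_signal_peptide
from pnpkit.processing import (
    CleavageSite,
    MaturePeptide,
    PrecursorAnnotation,
    ProcessingConfig,
    annotate_precursor,
    build_pfm,
    detect_cleavage_sites,
    liberate_peptides,
    match_ms_evidence,
    qualify_precursor,
    scan_repeat_motif,
)

CFG = ProcessingConfig()


def _prot(seq, ident="p"):
    return SequenceRecord(ident, seq, PROTEIN)


def _sp(ident, end):
    return SignalPeptideAnnotation(ident, end, 0.9, "imported")


# ---------------------------------------------------------------------------
# cleavage sites


def test_dibasic_site_detected():
    sites = detect_cleavage_sites("AAAKRAAA", CFG)
    assert sites == [CleavageSite(4, 5, "dibasic")]


def test_multibasic_run_is_single_greedy_site():
    sites = detect_cleavage_sites("AAARKRRA", CFG)
    assert sites == [CleavageSite(4, 7, "multibasic")]


def test_monobasic_toggle():
    cfg_off = ProcessingConfig(monobasic_enabled=False)
    assert detect_cleavage_sites("AAARAAA", cfg_off) == []
    assert detect_cleavage_sites("AAARAAA", CFG) == [CleavageSite(4, 4, "monobasic")]


def test_dibasic_pair_restriction():
    cfg = ProcessingConfig(dibasic_pairs=("KR",))
    assert detect_cleavage_sites("AAKKAA", cfg) == []
    assert detect_cleavage_sites("AAKRAA", cfg) == [CleavageSite(3, 4, "dibasic")]


def test_cleavage_sites_match_run_length_encoding_oracle():
    """Spans equal an RLE oracle over the K/R indicator string (500 seqs)."""
    rng = random.Random(31)
    for _ in range(500):
        seq = "".join(rng.choice("ACDKRGS") for _ in range(rng.randint(1, 80)))
        expected = [
            (m.start() + 1, m.end()) for m in re.finditer(r"[KR]+", seq)
        ]
        got = detect_cleavage_sites(seq, CFG)
        assert [(s.start, s.end) for s in got] == expected
        for s in got:
            kind = {1: "monobasic", 2: "dibasic"}.get(s.length, "multibasic")
            assert s.kind == kind


# ---------------------------------------------------------------------------
# liberation


def test_fmrfamide_style_chain_yields_two_amidated_copies():
    prot = _prot("FMRFGKRFMRFGKK")
    sites = detect_cleavage_sites(prot.sequence, CFG)
    peps = liberate_peptides(prot, None, sites, CFG)
    assert [p.sequence for p in peps] == ["FMRF", "FMRF"]
    assert all(p.amidated for p in peps)
    assert [(p.start, p.end) for p in peps] == [(1, 4), (8, 11)]


def test_leading_gln_flags_pyroglutamination_and_is_retained():
    prot = _prot("QSGFLGKR")
    peps = liberate_peptides(prot, None, detect_cleavage_sites(prot.sequence, CFG), CFG)
    assert len(peps) == 1
    assert peps[0].sequence == "QSGFL"
    assert peps[0].amidated and peps[0].pyroglutaminated


def test_precursor_terminal_glycine_is_not_an_amidation_signature():
    prot = _prot("AAAKRPEPG")
    peps = liberate_peptides(prot, None, detect_cleavage_sites(prot.sequence, CFG), CFG)
    assert peps[-1].sequence == "PEPG"
    assert not peps[-1].amidated


def test_liberation_respects_signal_peptide_and_min_length():
    # SP covers residues 1-5; AA after the first KR is below min length
    prot = _prot("MLLLLFFQDKRAAKRGSGSG")
    peps = liberate_peptides(
        prot, _sp("p", 5), detect_cleavage_sites(prot.sequence, CFG), CFG
    )
    assert [p.sequence for p in peps] == ["FFQD", "GSGSG"]
    assert peps[0].post_sp_start == 1


def test_monobasic_sites_cut_only_when_enabled():
    prot = _prot("AAAARTTTTSKRCCCC")
    sites = detect_cleavage_sites(prot.sequence, CFG)
    default = liberate_peptides(prot, None, sites, CFG)
    assert [p.sequence for p in default] == ["AAAARTTTTS", "CCCC"]
    cutting = liberate_peptides(
        prot, None, sites, ProcessingConfig(cleave_monobasic=True)
    )
    assert [p.sequence for p in cutting] == ["AAAA", "TTTTS", "CCCC"]
    assert "monobasic" in cutting[0].notes


def test_overlapping_sites_rejected():
    prot = _prot("AAKRAA")
    with pytest.raises(ValueError):
        liberate_peptides(
            prot, None,
            [CleavageSite(3, 4, "dibasic"), CleavageSite(4, 5, "dibasic")], CFG,
        )


def test_peptide_spans_are_disjoint_ordered_and_in_place(small_synthetic_set):
    """Conservation of residues: every reported peptide sits verbatim at its
    span; spans are pairwise disjoint and N-to-C ordered."""
    _, _, proteins, truth = small_synthetic_set
    for prot, t in zip(proteins, truth.precursors):
        sp = predict_signal_peptide(prot)
        peps = liberate_peptides(
            prot, sp, detect_cleavage_sites(prot.sequence, CFG), CFG
        )
        prev_end = 0
        for p in peps:
            assert prot.sequence[p.start - 1 : p.end] == p.sequence
            assert p.start > prev_end
            prev_end = p.end
            if p.amidated:  # removed glycine abuts the span
                assert prot.sequence[p.end] == "G"


# ---------------------------------------------------------------------------
# repeat motif


def test_repeat_motif_examples():
    matches, repetitive = scan_repeat_motif("AAAKKGGGGKRCCCCKK", CFG)
    assert len(matches) == 3 and repetitive
    assert scan_repeat_motif("AAKK", CFG) == ([], False)
    # 11-residue spacer exceeds the literal 3-10 window
    assert scan_repeat_motif("C" * 11 + "KR", CFG) == ([], False)
    # second basic residue must follow a K, not an R
    assert scan_repeat_motif("AAAARK", CFG) == ([], False)


def test_repeat_motif_matches_regex_oracle():
    """Match sets equal a regular-expression oracle on 1,000 random seqs."""
    rng = random.Random(5)
    pattern = re.compile(r"(?:(?<=[KR])|^)[^KR]{3,10}K[KR]")
    for _ in range(1000):
        seq = "".join(rng.choice("AGSKRC") for _ in range(rng.randint(0, 60)))
        expected = [(m.start() + 1, m.end()) for m in pattern.finditer(seq)]
        matches, repetitive = scan_repeat_motif(seq, CFG)
        assert matches == expected
        assert repetitive == (len(matches) >= 2)


def test_repeat_motif_invariant_under_spacer_substitution():
    base = "AAAKKGGGGKRCCCCKK"
    swapped = base.replace("G", "W").replace("C", "Y").replace("A", "P")
    assert scan_repeat_motif(base, CFG)[0] == scan_repeat_motif(swapped, CFG)[0]


# ---------------------------------------------------------------------------
# position frequency matrices


def test_pfm_identical_peptides():
    pfm = build_pfm(["FMRF", "FMRF"])
    for k, col in enumerate(pfm.columns):
        assert pfm.support[k] == 2
        assert max(col) == pytest.approx(1.0)


def test_pfm_right_justification_and_support():
    pfm = build_pfm(["ARF", "RF"])
    assert pfm.frequency(-1, "F") == pytest.approx(1.0)
    assert pfm.support[0] == 2
    assert pfm.frequency(-3, "A") == pytest.approx(1.0)
    assert pfm.support[2] == 1
    # support never increases toward the N-terminus
    assert list(pfm.support) == sorted(pfm.support, reverse=True)


def test_pfm_requires_two_peptides():
    with pytest.raises(ValueError):
        build_pfm(["FMRF"])


def test_pfm_matches_counting_oracle():
    """Frequencies equal brute-force per-column counting on 30 random peptides."""
    rng = random.Random(19)
    peptides = [
        "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(2, 12)))
        for _ in range(30)
    ]
    pfm = build_pfm(peptides)
    for k in range(len(pfm.columns)):
        contributing = [p for p in peptides if len(p) > k]
        assert pfm.support[k] == len(contributing)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            expected = sum(p[-(k + 1)] == aa for p in contributing) / len(contributing)
            assert pfm.frequency(-(k + 1), aa) == pytest.approx(expected)
        assert float(np.sum(pfm.columns[k])) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# MS evidence


def _ms_row(seq, ami=0, pyro=0):
    return AnnotationRow(seq, (seq, ami, pyro), "ms_peptide")


def test_ms_evidence_levels():
    predicted = [
        MaturePeptide("p", 1, 4, "FMRF", amidated=True),
        MaturePeptide("p", 6, 15, "QSGFLRESAM", pyroglutaminated=True),
        MaturePeptide("p", 17, 20, "AAAA"),
    ]
    observed = [_ms_row("FMRF", ami=1), _ms_row("GFLRE")]
    out = match_ms_evidence(predicted, observed)
    assert [p.ms_evidence for p in out] == ["full", "partial", "none"]
    # inputs untouched
    assert all(p.ms_evidence == "none" for p in predicted)


def test_ms_flag_contradiction_blocks_full_match():
    predicted = [MaturePeptide("p", 1, 4, "FMRF", amidated=False)]
    out = match_ms_evidence(predicted, [_ms_row("FMRF", ami=1)])
    assert out[0].ms_evidence == "none"


def test_ms_empty_observed_list():
    predicted = [MaturePeptide("p", 1, 4, "FMRF")]
    assert [p.ms_evidence for p in match_ms_evidence(predicted, [])] == ["none"]


# ---------------------------------------------------------------------------
# qualification


def _annotation(seq="AAAGKRBBB".replace("B", "F"), with_sp=True, peptides=(), repetitive=False):
    prot = _prot(seq, "q1")
    return PrecursorAnnotation(
        protein=prot,
        sp=_sp("q1", 5) if with_sp else None,
        sites=detect_cleavage_sites(prot.sequence, CFG),
        peptides=list(peptides),
        repetitive=repetitive,
    )


def test_qualify_repetitive_precursor():
    ann = qualify_precursor(_annotation(repetitive=True))
    assert ann.qualified
    assert "structural" in ann.evidence
    assert ann.rejection_reasons == []


def test_qualify_rejects_missing_signal_peptide():
    ann = qualify_precursor(_annotation(with_sp=False, repetitive=True))
    assert not ann.qualified
    assert ann.rejection_reasons == ["no signal peptide"]


def test_qualify_requires_at_least_one_criterion():
    ann = qualify_precursor(_annotation())
    assert not ann.qualified
    assert "no supporting evidence" in ann.rejection_reasons


def test_qualify_rejects_conflicting_domain():
    domain = AnnotationRow("q1", ("q1", "Trypsin", 10, 40), "domain_hit")
    ann = qualify_precursor(_annotation(repetitive=True), [domain])
    assert not ann.qualified
    assert any("Trypsin" in r for r in ann.rejection_reasons)


def test_qualify_cys_rich_counts_as_structural():
    pep = MaturePeptide("q1", 6, 10, "ACCFA", cys_count=2)
    ann = qualify_precursor(_annotation(peptides=[pep]))
    assert ann.qualified and "structural" in ann.evidence


# ---------------------------------------------------------------------------
# end-to-end recovery on synthetic precursors


def test_end_to_end_truth_recovery(small_synthetic_set):
    """Every generated peptide is recovered with sequence, span and flags."""
    _, _, proteins, truth = small_synthetic_set
    for prot, t in zip(proteins, truth.precursors):
        ann = annotate_precursor(prot, predict_signal_peptide(prot))
        predicted = {
            (p.sequence, p.start, p.end, p.amidated, p.pyroglutaminated, p.cys_count)
            for p in ann.peptides
        }
        for q in t.peptides:
            assert (
                q.sequence, q.start, q.end, q.amidated, q.pyroglutaminated, q.cys_count
            ) in predicted
        if len(t.peptides) >= 2:
            assert ann.qualified and "structural" in ann.evidence
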