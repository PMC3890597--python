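"""Similarity cluster maps and motif-based peptide family assignment.

Pairwise similarity hits (BLAST tabular, computed externally) are reduced to
an undirected graph: best e-value per unordered pair, edges kept strictly
below a threshold, families read off as connected components. Peptides are
additionally assigned to named families by a small curated motif table; the
motif grammar is deliberately smaller than full regular expressions so the
curated patterns stay auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .io import AnnotationRow
from .processing import MaturePeptide

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SimilarityEdge:
    """Best similarity hit between two distinct sequences."""

    a: str
    b: str
    evalue: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edges are not allowed")
        if self.evalue <= 0:
            raise ValueError("e-value must be positive")


@dataclass(frozen=True)
class ClusterMap:
    """Threshold-filtered similarity graph and its connected components."""

    nodes: frozenset
    edges: tuple[SimilarityEdge, ...]
    threshold: float
    components: tuple[frozenset, ...]
    singletons_removed: bool

    def component_of(self, node: str) -> Optional[frozenset]:
        for comp in self.components:
            if node in comp:
                return comp
        return None


def build_cluster_map(
    hits: Sequence[AnnotationRow], threshold: float, drop_singletons: bool = False
) -> ClusterMap:
    """Build a cluster map from 12-column similarity hits.

    Self-hits are ignored; the minimum e-value per unordered pair is kept;
    edges survive when evalue < threshold (strict, matching "P value <
    1e-10" style cutoffs). Components are computed by transitive
    connectivity; singleton components can be dropped, as the published
    maps remove unconnected sequences.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for row in hits:
        q, s = str(row.columns[0]), str(row.columns[1])
        ev = float(row.columns[10])
        nodes.update((q, s))
        if q == s:
            continue
        key = (q, s) if q < s else (s, q)
        if key not in best or ev < best[key]:
            best[key] = ev

    edges = tuple(
        SimilarityEdge(a, b, ev)
        for (a, b), ev in sorted(best.items())
        if ev < threshold
    )
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from((e.a, e.b) for e in edges)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    if drop_singletons:
        components = [c for c in components if len(c) >= 2]
        nodes = set().union(*components) if components else set()
    components.sort(key=lambda c: sorted(c)[0])
    return ClusterMap(
        frozenset(nodes), edges, threshold, tuple(components), drop_singletons
    )


_TOKEN = re.compile(r"x\{(\d+),(\d+)\}|x\{(\d+)\}|\[([A-Z]+)\]|x|([A-Z])|\$")


@dataclass(frozen=True)
class FamilyMotif:
    """A curated family motif.

    Grammar: fixed residues (``F``), the wildcard ``x``, bracketed residue
    classes (``[GIL]``), ranged spacers (``x{6,7}``), and an optional ``$``
    anchoring the match at the C-terminus. ``requires_amidation`` restricts
    the family to amidated peptides.
    """

    family_name: str
    pattern: str
    requires_amidation: bool = False
    _regex: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", _compile_motif(self.pattern))

    def matches(self, peptide: MaturePeptide) -> bool:
        if self.requires_amidation and not peptide.amidated:
            return False
        if self._regex.search(peptide.sequence):
            return True
        # amidated peptides had their signature glycine removed during
        # liberation; motifs printed against the precursor form (e.g. the
        # Wamide C-terminal [G/I/L]) are also tried with the G restored
        if peptide.amidated and self._regex.search(peptide.sequence + "G"):
            return True
        return False


def _compile_motif(pattern: str) -> re.Pattern:
    pos = 0
    out: list[str] = []
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"unparseable motif {pattern!r} at position {pos}")
        tok = m.group(0)
        if tok == "$":
            if m.end() != len(pattern):
                raise ValueError(f"'$' must terminate the motif {pattern!r}")
            out.append("$")
        elif tok == "x":
            out.append("[A-Z]")
        elif tok.startswith("x{"):
            if m.group(3) is not None:
                out.append("[A-Z]{%s}" % m.group(3))
            else:
                out.append("[A-Z]{%s,%s}" % (m.group(1), m.group(2)))
        elif tok.startswith("["):
            out.append("[%s]" % m.group(4))
        else:
            out.append(tok)
        pos = m.end()
    return re.compile("".join(out))


def default_motif_table() -> list[FamilyMotif]:
    """The shipped curated motif table (user-extensible).

    Covers the printed family motifs: the myoinhibitory peptide (Wamide/MIP)
    pattern x-W-x(6,7)-W-[G/I/L] and the C-terminally amidated families
    RFamide (R[F/Y]-amide), FVamide, RGWamide and FVRIamide. Order matters:
    the first matching motif wins, so the more specific C-terminal motifs
    precede the short ones.
    """
    return [
        FamilyMotif("FVRIamide", "FVRI$", requires_amidation=True),
        FamilyMotif("RGWamide", "RGW$", requires_amidation=True),
        FamilyMotif("Wamide/MIP", "xWx{6,7}W[GIL]$", requires_amidation=False),
        FamilyMotif("RFamide", "R[FY]$", requires_amidation=True),
        FamilyMotif("FVamide", "FV$", requires_amidation=True),
    ]


def assign_family(
    peptides: Sequence[MaturePeptide], motifs: Optional[Sequence[FamilyMotif]] = None
) -> list[str]:
    """Assign each peptide to the first matching motif's family.

    Returns one family name (or ``"unassigned"``) per input peptide, in
    input order.
    """
    if motifs is None:
        motifs = default_motif_table()
    names = [m.family_name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("family names must be unique in the motif table")
    out = []
    for pep in peptides:
        for motif in motifs:
            if motif.matches(pep):
                out.append(motif.family_name)
                break
        else:
            out.append(UNASSIGNED)
    return out


def precursor_family(
    peptides: Sequence[MaturePeptide], assignments: Sequence[str]
) -> dict[str, str]:
    """Precursor-level family: the modal family among a precursor's peptides.

    Ties (including all-unassigned) resolve to ``"unassigned"``.
    """
    per_precursor: dict[str, list[str]] = {}
    for pep, fam in zip(peptides, assignments):
        per_precursor.setdefault(pep.precursor_id, []).append(fam)
    out: dict[str, str] = {}
    for pid, fams in per_precursor.items():
        named = [f for f in fams if f != UNASSIGNED]
        if not named:
            out[pid] = UNASSIGNED
            continue
        counts: dict[str, int] = {}
        for f in named:
            counts[f] = counts.get(f, 0) + 1
        top = max(counts.values())
        winners = [f for f, c in counts.items() if c == top]
        out[pid] = winners[0] if len(winners) == 1 else UNASSIGNED
    return out
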