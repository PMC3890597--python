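# Methods

## Scope and model

`pnpkit` annotates proneuropeptides (pNPs): secreted precursor proteins
carrying an N-terminal signal peptide (SP) and one or more peptide elements
flanked by basic cleavage sites. The pipeline is a chain of deterministic
sequence operations — ORF calling, SP gating, convertase-site processing,
motif classification — followed by count normalization and clustering for
stage expression profiles. External heavy lifting (SP neural predictors,
BLAST/PSI-BLAST, domain scans, spectral search) is *imported* as tables;
the package's contribution is everything downstream of those tables.

## ORF calling

All six frames are translated with the standard genetic code (stops
TAA/TAG/TGA; any codon containing N renders X). ATG-initiated ORFs (ATG to
stop or to the frame end) are preferred; when none reaches the length
cutoff, the longest stop-free stretch is accepted as an open-ended ORF.
This fallback exists because EST/454 transcripts are often 5′-truncated;
it is on by default and recorded in the ORF's `initiator` field. Ties
resolve by frame order +1,+2,+3,−1,−2,−3, then by position. The proteome
cutoff defaults to 120 aa for real transcriptomes; the synthetic analyses
use 20 aa because generated precursors are deliberately compact.

## Signal-peptide heuristic

When no external SP call is imported, an SP is called inside residues 1–45
if (a) the net charge of residues 1–5 is ≥ 0, and (b) the window contains a
hydrophobic core: the *first maximal run* of ≥ 6 consecutive residues from
the Kyte–Doolittle ≥ 1.8 set {A,C,F,I,L,M,V} whose mean hydropathy exceeds
1.6. The cleavage position is the first position p after the core with
small/neutral residues ({A,G,S,C,T,V}) at −1 (p) and −3 (p−2) — the
classic (−3,−1) rule. The score maps core hydropathy into [0,1] as
min(1, (mean − 1.6)/2.9): bounded and monotone; the calibration is a
convenience, not a claim. Defining the core as a residue-level run (rather
than a best-mean window) keeps the cleavage search anchored at the core's
true C-terminal edge instead of drifting into the mature chain.

## Precursor processing

*Cleavage sites.* Maximal K/R runs are single cleavage events: length 1 =
monobasic, 2 = dibasic (filtered by the configured ordered pairs; all of
KR/RR/KK/RK by default), ≥ 3 = multibasic. Treating a run as one event
avoids spurious single-residue peptides.

*Liberation.* Segments lie strictly between the SP end, the basic runs and
the C-terminus. A trailing G immediately before a basic run is removed and
flags amidation; a precursor-terminal G is *not* a signature (the
enzymatic route needs the glycine-extended intermediate before cleavage).
A leading Q flags pyroglutamination but is retained so sequences stay
matchable against MS lists (E is not treated as a pyroGlu donor). Segments
below `min_peptide_length` (default 3) are dropped. Coordinates are
1-based inclusive, reported in both full-precursor and post-SP frames.

*Monobasic policy.* Monobasic sites are detected and reported by default,
but liberation splits only at di-/multibasic runs unless
`cleave_monobasic` is set. Monobasic processing is biologically selective
(myomodulin-type precursors), and unconditional monobasic cutting would
shred peptides with internal arginines — e.g. every RFamide. When enabled,
monobasic-derived peptides carry a `monobasic` provenance note.

*Repeat scan.* The discovery motif `x(3–10)-K[K/R]` is applied literally:
a maximal K/R-free run of 3–10 residues immediately followed by K then
K/R, scanned left to right without overlap; `repetitive` means ≥ 2 matches
(the threshold is configurable; 2 is a documented default, not a claim).
Longer repeat peptides (e.g. the ~12-residue DH44 copies) fall outside the
window by design — they are still recovered by liberation, so no
sensitivity is lost pipeline-wide.

*Logos.* Position frequency matrices anchor at the C-terminus
(right-justified, no gaps, no pseudocounts); column −k is computed over
peptides of length ≥ k, so support is non-increasing toward the
N-terminus.

*MS evidence.* `full` requires sequence equality with no contradiction of
the amidation/pyroGlu flags; `partial` requires an observed sequence of
length ≥ 5 contained in the prediction.

*Qualification.* qualified = SP present ∧ ≥ 1 cleavage site ∧ no
conflicting domain hit ∧ ≥ 1 evidence class, with structural evidence
granted automatically for repetitive architecture, amidated or
pyroglutaminated peptides, or ≥ 2 Cys in a peptide. Every failed conjunct
is listed as a rejection reason.

## Classification

Cluster maps import BLAST-tabular hits: the best e-value per unordered
pair is kept, edges survive strictly below the threshold (matching
"P value < 1e-10"-style legends), components are transitive connectivity
(networkx), and singleton components can be dropped as in the published
maps. The two-stage map (iterative-search map, then re-clustering of the
dense centre with plain BLAST at 1e-5) is expressed as two calls on two
hit files; centre selection is a user-supplied node list because it was a
visual judgement in the original workflow. The motif grammar (fixed
residues, `[..]` classes, `x{m,n}` spacers, `$` anchor, optional amidation
requirement) is deliberately weaker than regular expressions so the
curated table stays auditable. Amidated peptides are matched both as
processed sequences and with the signature G restored, so precursor-form
motifs like the Wamide/MIP `xWx{6,7}W[GIL]$` apply. Precursor-level family
is the modal peptide family, ties → unassigned.

## Expression profiling

rpm[g,s] = raw/library_size × 1e6; RPKM additionally divides by gene
length in kb. The retention rule keeps genes with ≥ 2 rpm in at least one
stage (inclusive). Clustering uses d = 1 − Pearson r with average linkage
by default (the published analysis names only the distance; linkage is a
flag), on RPKM values when lengths are available (also a flag — the
original analysis applied both normalizations without stating which fed
the distance). Zero-variance rows get distance 1 to everything rather than
an error, so constant low-expressors remain clusterable. Genes are sorted
lexicographically before clustering, which makes the dendrogram invariant
to input order. "Fraction of 1" is row-sum normalization (all-zero rows
stay zero); row-max normalization is available behind a flag since the
published caption is ambiguous.

## Synthetic data

The generator emits precursors with the architecture SP + acidic spacer +
basic run + (peptide [+G] + basic run)* + short tail, and transcripts as
uniform synonymous reverse-translations (ATG start, one stop, no internal
stops, no UTRs). Defaults: 1–16 copies of 4–18-residue peptides, 15–30
residue SPs, amidation 0.5, pyroGlu 0.15, Cys-rich 0.1, spacers 2–12 —
rates typical of annelid pNP catalogues, chosen once. Constructions that
keep ground truth unambiguous: peptides/spacers contain no K/R (RFamide
peptides excepted, whose internal R is deliberately left uncut by the
monobasic policy), non-amidated peptides never end in G, only pyroGlu
peptides start with Q, spacers never end in G, and the first peptide of
every multi-copy precursor is amidated (repeat families are overwhelmingly
amidated; this also guarantees structural evidence for multi-copy
precursors). SPs are built to be exactly recoverable by the heuristic so
processing tests are isolated from SP-prediction accuracy.

Expression matrices draw Poisson counts (no overdispersion — simplicity
over realism; negative-binomial noise would be the next step) around
single-bump cluster mean profiles over 13 stages, with library sizes of
0.5–2 M reads. What passing synthetic tests do *not* show: robustness to
assembly chimeras, sequencing error, codon bias, truncated SPs, atypical
cleavage contexts, or overdispersed counts.

`pnpkit.synthetic_reference` holds stand-ins for the study's deposited
objects, built to their published summary structure: two DH44-like
precursors whose 13 and 16 glycine-extended, dibasic-flanked repeats are
construction targets (the deposited sequences themselves are not
bundled), and a 98-gene × 13-stage integer count table in which exactly 79
genes reach 2 rpm, four of them exactly at the boundary. These exercise
the liberation and filter code paths end to end; they are not the study's
data.

## Numerical choices and limitations

Agglomeration is scipy's UPGMA on the condensed Pearson-distance matrix
(verified in tests against a naive O(n³) oracle); distances are clipped to
[0, 2] and symmetrized against floating-point drift. PFM columns must sum
to 1 within 1e-9. Problem sizes in the shipped analyses (200 precursors,
98 × 13 and 60 × 13 matrices) are desk-scale choices; all operations scale
linearly in sequence length except clustering (quadratic in genes).
Stop-codon read-through precursors (a known FVamide/EFLGamide special
case) are handled by annotating a second user-supplied chain, not by
automatic translation through stops. Disulfide connectivity is not
predicted (Cys counting only), and no 2-D force-directed layout is
computed for cluster maps (components only).
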