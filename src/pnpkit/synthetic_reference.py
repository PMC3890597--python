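"""Synthetic stand-ins for the study's deposited reference data.

The original study ships its reference objects as supplementary downloads:
the proneuropeptide FASTA including the two highly repetitive diuretic
hormone 44 (DH44) precursors, and the normalized read-count table for 98
proneuropeptide genes across 13 life-cycle stages. Those downloads are not
bundled here; this module constructs *synthetic* stand-ins with the same
published summary structure — two DH44-like precursors carrying 13 and 16
amidated peptide copies, and a 98-gene x 13-stage count table in which 79
genes reach at least 2 reads per million in at least one stage — so the
cleavage/liberation and expression-filter code paths can be exercised
end-to-end at desk scale. Every object produced here is synthetic; none of
the sequences or counts are the study's own data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import RAW, CountMatrix
from .io import PROTEIN, SequenceRecord

# The 13 life-cycle stages profiled by the study, egg to mature adults.
STAGE_NAMES = (
    "egg", "24hpf", "36hpf", "48hpf", "72hpf", "4dpf", "10dpf", "15dpf",
    "1month_preCM", "1month_postCM", "3month_atokous", "male", "female",
)

N_GENES = 98
N_RETAINED_AT_2RPM = 79

# An ELH/DH44-flavoured 11-residue consensus: no K/R (so the only cleavage
# sites are the engineered dibasic runs), no C, does not end in G.
_DH44_CONSENSUS = "SGMGGLASSSV"
_VARIANT_POOL = "ASTGNQEDHLV"

_SIGNAL_PEPTIDE = "MKLLFLILLFILASA"  # heuristic recovers sp_end = 15 exactly


def _peptide_variants(n: int, rng: np.random.Generator) -> list[str]:
    """n distinct single/double-substitution variants of the consensus."""
    variants: list[str] = []
    seen = {None}
    while len(variants) < n:
        body = list(_DH44_CONSENSUS)
        for _ in range(int(rng.integers(1, 3))):
            pos = int(rng.integers(1, len(body) - 1))  # keep termini fixed
            body[pos] = _VARIANT_POOL[int(rng.integers(len(_VARIANT_POOL)))]
        seq = "".join(body)
        if seq not in seen:
            seen.add(seq)
            variants.append(seq)
    return variants


def dh44_like_precursors(seed: int = 44) -> tuple[SequenceRecord, SequenceRecord]:
    """Two synthetic DH44-like precursors with 13 and 16 peptide copies.

    Architecture per the published precursor schematics: signal peptide,
    then repeated amidated peptide copies, each glycine-extended and
    flanked by dibasic cleavage sites. The short acidic spacer and tail
    fall below the minimum peptide length, so liberation yields exactly
    the 13 and 16 peptide copies.
    """
    rng = np.random.default_rng(seed)
    records = []
    for name, n_copies in (("DH44-1", 13), ("DH44-2", 16)):
        parts = [_SIGNAL_PEPTIDE, "DE", "KR"]
        for pep in _peptide_variants(n_copies, rng):
            parts.append(pep + "G" + "KR")
        parts.append("PE")
        records.append(
            SequenceRecord(
                name, "".join(parts), PROTEIN,
                f"synthetic DH44-like precursor, {n_copies} peptide copies",
            )
        )
    return records[0], records[1]


def synthetic_pnp_count_table(seed: int = 27) -> CountMatrix:
    """A synthetic 98-gene x 13-stage raw count matrix.

    Constructed so that exactly 79 genes carry >= 2 reads per million in at
    least one stage (the published filter outcome), the remaining 19 staying
    strictly below. Counts are integers; library sizes fall in the
    0.8-1.5 M read range.
    """
    rng = np.random.default_rng(seed)
    libs = rng.integers(800_000, 1_500_000, size=len(STAGE_NAMES)).astype(float)
    counts = np.zeros((N_GENES, len(STAGE_NAMES)))
    for g in range(N_GENES):
        peak_stage = int(rng.integers(len(STAGE_NAMES)))
        lib = libs[peak_stage]
        if g < N_RETAINED_AT_2RPM:
            # peak comfortably (or exactly) at/above the 2-rpm boundary
            base = int(np.ceil(2.0 * lib / 1e6))
            peak = base if g < 4 else base + int(rng.integers(0, 400))
        else:
            # peak strictly below 2 rpm in every stage
            peak = max(0, int(np.floor(2.0 * lib / 1e6)) - 1 - int(rng.integers(0, 2)))
        counts[g, peak_stage] = peak
        for s in range(len(STAGE_NAMES)):
            if s != peak_stage:
                # other stages scaled so their rpm never exceeds the peak's
                cap = int(np.floor(peak * libs[s] / lib))
                counts[g, s] = int(rng.integers(0, cap + 1)) if cap > 0 else 0
    gene_ids = [f"pnp{g + 1:03d}" for g in range(N_GENES)]
    data = pd.DataFrame(counts, index=gene_ids, columns=list(STAGE_NAMES))
    lengths = pd.Series(
        rng.integers(400, 2500, size=N_GENES).astype(float), index=gene_ids
    )
    return CountMatrix(
        data=data,
        library_sizes=pd.Series(libs, index=list(STAGE_NAMES)),
        lengths=lengths,
        normalization=RAW,
    )
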