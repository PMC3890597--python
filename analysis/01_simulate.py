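#!/usr/bin/env python
"""Generate the synthetic benchmark: 200 precursor transcripts with ground
truth and a 13-stage count matrix, written under results/simulated/."""

import json
from pathlib import Path

from pnpkit.io import write_fasta, write_table
from pnpkit.simulate import GeneratorConfig, generate_expression_matrix, generate_precursor_set

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(n_precursors=200, seed=3)
    transcripts, proteins, truth = generate_precursor_set(config)
    write_fasta(transcripts, OUT / "transcripts.fasta")
    write_fasta(proteins, OUT / "proteins.fasta")
    matrix, xtruth = generate_expression_matrix(config)
    matrix.data.to_csv(OUT / "counts.tsv", sep="\t")
    write_table(list(matrix.library_sizes.items()), OUT / "library_sizes.tsv")
    write_table(list(matrix.lengths.items()), OUT / "lengths.tsv")
    (OUT / "truth_summary.json").write_text(json.dumps({
        "n_precursors": len(proteins),
        "n_truth_peptides": sum(len(p.peptides) for p in truth.precursors),
        "n_repetitive": sum(p.repetitive for p in truth.precursors),
        "expression_clusters": sorted(set(xtruth.expression.cluster_labels)),
    }, indent=2))
    print(f"wrote {len(proteins)} precursors and a "
          f"{matrix.data.shape[0]}x{matrix.data.shape[1]} count matrix to {OUT}")


if __name__ == "__main__":
    main()
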