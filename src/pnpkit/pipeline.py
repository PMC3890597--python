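"""Pipeline orchestration: transcriptome -> proteome -> secretome ->
precursor processing -> classification -> expression profiling.

Outputs are a pure function of (inputs, config, seed). Every run writes a
manifest listing each output file with its row count and a hash of the
effective configuration; a failing stage leaves its partial outputs behind
with a ``.partial`` suffix and returns a non-zero status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import expression as xp
from . import families as fam
from .io import (
    NUCLEOTIDE, PROTEIN, SequenceRecord, read_fasta, read_table, write_fasta,
    write_table,
)
from .orfs import (
    SignalPeptideAnnotation, find_longest_orf, make_secretome_record,
    predict_signal_peptide,
)
from .processing import ProcessingConfig, annotate_precursor

log = logging.getLogger("pnpkit")


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a full pipeline run."""

    transcripts: Optional[str] = None
    proteins: Optional[str] = None
    sp_table: Optional[str] = None
    ms_table: Optional[str] = None
    domain_table: Optional[str] = None
    hits_table: Optional[str] = None
    counts: Optional[str] = None
    library_sizes: Optional[str] = None
    lengths: Optional[str] = None
    outdir: str = "pipeline_out"
    min_protein_length: int = 120
    allow_open_ended: bool = True
    cluster_threshold: float = 1e-10
    drop_singletons: bool = True
    min_rpm: float = 2.0
    clustering_values: str = "rpkm"  # or "rpm"
    linkage: str = "average"
    fraction_mode: str = "sum"
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        proc = ProcessingConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("processing", {}) or {}).items()
        })
        return cls(processing=proc, **raw)

    def config_hash(self) -> str:
        payload = {**self.__dict__}
        payload["processing"] = self.processing.__dict__.copy()
        payload["processing"]["dibasic_pairs"] = list(self.processing.dibasic_pairs)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_sp_table(path: Optional[str]) -> dict[str, int]:
    if path is None:
        return {}
    return {
        row.subject_id: int(row.columns[1])
        for row in read_table(path, "signal_peptide")
    }


def derive_proteome(
    transcripts: list[SequenceRecord], min_protein_length: int
) -> list[SequenceRecord]:
    """Longest-ORF translation of every transcript passing the length cutoff."""
    proteome = []
    for tr in transcripts:
        orf = find_longest_orf(tr, min_protein_length)
        if orf is not None:
            proteome.append(
                SequenceRecord(
                    tr.identifier, orf.protein, PROTEIN,
                    f"frame {orf.frame:+d} {orf.nt_start}-{orf.nt_end} {orf.initiator}",
                )
            )
    return proteome


def derive_secretome(
    proteome: list[SequenceRecord], imported_sp: dict[str, int]
) -> tuple[list[SequenceRecord], dict[str, SignalPeptideAnnotation]]:
    """SP gating plus in-silico SP removal."""
    secretome = []
    sp_calls: dict[str, SignalPeptideAnnotation] = {}
    for prot in proteome:
        imported = None
        if prot.identifier in imported_sp:
            imported = SignalPeptideAnnotation(
                prot.identifier, imported_sp[prot.identifier], 1.0, "imported"
            )
        sp = predict_signal_peptide(prot, imported)
        if sp is None:
            continue
        sp_calls[prot.identifier] = sp
        secretome.append(make_secretome_record(prot, sp))
    return secretome, sp_calls


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Execute every configured stage; returns (exit status, manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "outputs": {}}

    def emit(name: str, rows: int) -> None:
        manifest["outputs"][name] = {"rows": rows}
        log.info("wrote %s (%d rows)", name, rows)

    current_stage = "setup"
    try:
        # ---- proteome -------------------------------------------------
        current_stage = "orfs"
        if config.proteins:
            proteome = read_fasta(config.proteins, PROTEIN)
        elif config.transcripts:
            transcripts = read_fasta(config.transcripts, NUCLEOTIDE)
            proteome = derive_proteome(transcripts, config.min_protein_length)
            path = outdir / "proteome.fasta"
            write_fasta(proteome, path)
            emit(path.name, len(proteome))
        else:
            raise FileNotFoundError("no transcripts or proteins input configured")

        # ---- secretome ------------------------------------------------
        current_stage = "secretome"
        secretome, sp_calls = derive_secretome(
            proteome, _load_sp_table(config.sp_table)
        )
        path = outdir / "secretome.fasta"
        write_fasta(secretome, path)
        emit(path.name, len(secretome))
        path = outdir / "signal_peptides.tsv"
        write_table(
            [(s.protein_id, s.sp_end, f"{s.score:.3f}", s.source)
             for s in sp_calls.values()],
            path, header=("protein_id", "sp_end", "score", "source"),
        )
        emit(path.name, len(sp_calls))

        # ---- precursor processing ------------------------------------
        current_stage = "process"
        observed = read_table(config.ms_table, "ms_peptide") if config.ms_table else []
        domains = read_table(config.domain_table, "domain_hit") if config.domain_table else []
        by_id = {p.identifier: p for p in proteome}
        annotations = []
        for ident, prot in by_id.items():
            if ident not in sp_calls:
                continue
            annotations.append(
                annotate_precursor(
                    prot, sp_calls[ident], config.processing, observed, domains
                )
            )
        pep_rows = []
        for ann in annotations:
            for p in ann.peptides:
                pep_rows.append((
                    p.precursor_id, p.start, p.end, p.post_sp_start, p.post_sp_end,
                    p.sequence, int(p.amidated), int(p.pyroglutaminated),
                    p.cys_count, p.ms_evidence, ";".join(p.notes),
                ))
        path = outdir / "peptides.tsv"
        write_table(pep_rows, path, header=(
            "precursor_id", "start", "end", "post_sp_start", "post_sp_end",
            "sequence", "amidated", "pyroglu", "cys_count", "ms_evidence", "notes",
        ))
        emit(path.name, len(pep_rows))

        qual_rows = [
            (ann.protein.identifier, len(ann.sites), len(ann.peptides),
             int(ann.repetitive), ",".join(sorted(ann.evidence)),
             int(ann.qualified), ";".join(ann.rejection_reasons))
            for ann in annotations
        ]
        path = outdir / "qualification.tsv"
        write_table(qual_rows, path, header=(
            "precursor_id", "n_sites", "n_peptides", "repetitive",
            "evidence", "qualified", "rejection_reasons",
        ))
        emit(path.name, len(qual_rows))
        manifest["n_peptides"] = len(pep_rows)
        manifest["n_qualified"] = sum(int(a.qualified) for a in annotations)

        # ---- family assignment ---------------------------------------
        current_stage = "families"
        peptides = [p for ann in annotations for p in ann.peptides]
        assignments = fam.assign_family(peptides)
        path = outdir / "peptide_families.tsv"
        write_table(
            [(p.precursor_id, p.sequence, a) for p, a in zip(peptides, assignments)],
            path, header=("precursor_id", "sequence", "family"),
        )
        emit(path.name, len(assignments))
        prec_fams = fam.precursor_family(peptides, assignments)
        path = outdir / "precursor_families.tsv"
        write_table(sorted(prec_fams.items()), path, header=("precursor_id", "family"))
        emit(path.name, len(prec_fams))

        # ---- cluster map ---------------------------------------------
        if config.hits_table:
            current_stage = "cluster"
            hits = read_table(config.hits_table, "similarity_hit")
            cmap = fam.build_cluster_map(
                hits, config.cluster_threshold, config.drop_singletons
            )
            rows = [
                (i + 1, ",".join(sorted(comp)))
                for i, comp in enumerate(cmap.components)
            ]
            path = outdir / "components.tsv"
            write_table(rows, path, header=("component", "members"))
            emit(path.name, len(rows))

        # ---- expression profiling ------------------------------------
        if config.counts and config.library_sizes:
            current_stage = "profile"
            matrix = xp.read_counts(config.counts, config.library_sizes, config.lengths)
            rpm = xp.normalize_counts(matrix, "rpm")
            totals = xp.stage_totals(rpm)
            path = outdir / "stage_totals.tsv"
            write_table(list(totals.items()), path, header=("stage", "total_rpm"))
            emit(path.name, len(totals))
            filtered = xp.filter_min_expression(rpm, config.min_rpm)
            path = outdir / "retained_genes.tsv"
            write_table([(g,) for g in filtered.gene_ids], path, header=("gene_id",))
            emit(path.name, len(filtered.gene_ids))
            manifest["n_genes_retained"] = len(filtered.gene_ids)
            values = filtered
            if config.clustering_values == "rpkm" and matrix.lengths is not None:
                raw_kept = xp.CountMatrix(
                    matrix.data.loc[filtered.gene_ids], matrix.library_sizes,
                    matrix.lengths, xp.RAW,
                )
                values = xp.normalize_counts(raw_kept, "rpkm")
            if len(values.data) >= 2:
                tree = xp.cluster_profiles(values, config.linkage)
                path = outdir / "merge_tree.tsv"
                write_table(
                    [tuple(row) for row in tree.merge_tree],
                    path, header=("left", "right", "height", "size"),
                )
                emit(path.name, len(tree.merge_tree))
    except Exception as exc:  # noqa: BLE001 - stage failures become exit status
        log.error("stage %s failed: %s", current_stage, exc)
        for name in list(manifest["outputs"]):
            src = outdir / name
            if src.exists():
                src.rename(outdir / f"{name}.partial")
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return 1, manifest

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return 0, manifest
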