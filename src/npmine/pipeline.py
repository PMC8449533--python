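"""End-to-end orchestration of the neuropeptide and GPCR tracks.

Both tracks are deterministic: re-running with an identical config and
seed produces byte-identical reports (logging goes to stderr only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import families, gpcr, seq_io
from .precursor import (
    CleavageRules,
    PtmRules,
    SignalConfig,
    annotate_precursor,
)

log = logging.getLogger("npmine")


@dataclass
class PipelineConfig:
    input_fasta: str
    alphabet: str = "nucleotide"  # of the input records
    outdir: Optional[str] = None
    min_orf_neuropeptide: int = 50
    min_orf_gpcr: int = 150
    signal_cfg: SignalConfig = field(default_factory=SignalConfig)
    cleavage_rules: CleavageRules = field(default_factory=CleavageRules)
    ptm_rules: PtmRules = field(default_factory=PtmRules)
    tm_cfg: gpcr.TmConfig = field(default_factory=gpcr.TmConfig)
    motif_library_tsv: Optional[str] = None
    reference_panel_fasta: Optional[str] = None
    seed: int = 0


def _proteins_for_track(cfg: PipelineConfig, min_orf: int) -> list[seq_io.ProteinRecord]:
    if cfg.alphabet == "protein":
        records = seq_io.read_fasta(cfg.input_fasta, "protein")
        log.info("read %d protein records", len(records))
        return records
    transcripts = seq_io.read_fasta(cfg.input_fasta, "nucleotide")
    log.info("read %d transcripts", len(transcripts))
    orfs = []
    for t in transcripts:
        orfs.extend(seq_io.find_orfs(t, min_len_aa=min_orf))
    log.info("found %d ORFs (min length %d aa)", len(orfs), min_orf)
    return orfs


def annotation_json(ann) -> dict:
    return {
        "protein_id": ann.protein_id,
        "signal": {
            "span": ann.signal.span,
            "score": ann.signal.score,
            "method": ann.signal.method,
        },
        "sites": [
            {"start": s.start, "run": s.basic_run, "kind": s.kind,
             "cut_after": s.cut_after}
            for s in ann.sites
        ],
        "fragments": [
            {"span": f.span, "seq": f.seq, "role": f.role} for f in ann.fragments
        ],
        "matures": [
            {"rendered": m.rendered, "seq": m.seq, "amidated": m.amidated,
             "pyroglu": m.pyroglu, "cys_count": m.cys_count,
             "source_span": m.source_span}
            for m in ann.matures
        ],
        "warnings": ann.warnings,
    }


def run_neuropeptide_track(cfg: PipelineConfig) -> dict:
    """ORF -> signal -> cleavage -> PTM -> family classification."""
    proteins = _proteins_for_track(cfg, cfg.min_orf_neuropeptide)
    annotations = [
        annotate_precursor(p, cfg.signal_cfg, cfg.cleavage_rules, cfg.ptm_rules)
        for p in proteins
    ]
    lib = families.compile_motif_library(cfg.motif_library_tsv)
    table, tally = families.classify_all(annotations, lib)
    log.info(
        "annotated %d precursors; %d mature peptides; %d classified",
        len(annotations),
        len(table),
        int((table["family"] != families.UNCLASSIFIED).sum()) if len(table) else 0,
    )
    result = {"annotations": annotations, "table": table, "tally": tally}
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        tally.to_csv(outdir / "family_tally.tsv", sep="\t", index=False)
        with open(outdir / "annotations.json", "w") as fh:
            json.dump([annotation_json(a) for a in annotations], fh, indent=1)
    return result


def run_gpcr_track(cfg: PipelineConfig) -> dict:
    """Length filter -> 7-TM triage -> family assignment -> NJ tree."""
    proteins = _proteins_for_track(cfg, cfg.min_orf_gpcr)
    retained, rejected = gpcr.filter_by_length(proteins, cfg.min_orf_gpcr)
    log.info("length filter: %d retained, %d rejected", len(retained), len(rejected))
    candidates = [gpcr.triage(p, cfg.tm_cfg) for p in retained]
    refs = []
    if cfg.reference_panel_fasta:
        panel = seq_io.read_fasta(cfg.reference_panel_fasta, "protein")
        refs = gpcr.parse_reference_fasta(panel)
    passing = [c for c in candidates if c.passes_7tm]
    if refs:
        for c in passing:
            gpcr.assign_family(c, refs)
    report = gpcr.candidate_report(candidates)
    rejected_report = pd.DataFrame(
        [{"id": p.id, "length": p.length} for p in rejected],
        columns=["id", "length"],
    )
    tree = None
    domains = {c.protein_id: c.domain_7tm for c in passing if c.domain_7tm}
    domains.update({rid: dom for rid, _fam, dom in refs})
    if len(domains) >= 3:
        dm = gpcr.distance_matrix(domains)
        tree = gpcr.nj_tree(dm)
    else:
        log.info("fewer than 3 domains; skipping tree construction")
    result = {
        "candidates": candidates,
        "report": report,
        "rejected": rejected_report,
        "tree": tree,
    }
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "gpcr_candidates.tsv", sep="\t", index=False)
        rejected_report.to_csv(outdir / "gpcr_rejected.tsv", sep="\t", index=False)
        if tree is not None:
            tree.write(str(outdir / "gpcr_tree.nwk"))
    return result
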