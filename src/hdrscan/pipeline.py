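"""End-to-end orchestration: filter -> FST scan -> HDR calling -> gene and
effect annotation -> expression ranking, from a single config, with
deterministic, machine-readable outputs.

Every stage writes its table so a run can be resumed or inspected stage by
stage, and a manifest records the parameters, seed and per-stage record
counts.  Identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import effects, expression, fstscan, genes as genes_mod, hdr as hdr_mod, variants
from .simdata import read_scaffold_lengths

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one scan run.

    The analysis parameters default to the scan's canonical settings: 10 kb
    windows advanced by 1 kb, top 0.1% of windows, genotypes kept only at
    DP > 3, fixation calls requiring 5 called samples per population, and an
    expression screen at rank percentile 50.
    """

    vcf: str
    fasta: str
    popmap: str
    outdir: str
    gff3: str | None = None
    counts: str | None = None
    lengths: str | None = None
    fai: str | None = None

    window_bp: int = 10_000
    step_bp: int = 1_000
    min_scaffold_bp: int = 10_000
    top_frac: float = 0.001
    min_dp: int = 4
    min_called: int = 5
    hard_filters: dict = field(default_factory=lambda: dict(variants.DEFAULT_HARD_FILTERS))
    tpm_rank_cutoff: float = 50.0
    expressed_min_tpm: float = 0.0
    cds_only_candidates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: PipelineConfig) -> dict:
    """Execute the full scan; returns the run manifest (also written as JSON).

    Outputs in ``outdir``: ``windows.tsv``, ``selected_windows.bed``,
    ``hdrs.bed``/``hdrs.tsv``, ``diverged_snvs.tsv``, ``candidate_genes.tsv``,
    ``amino_acid_changes.tsv``, ``expression_ranks.tsv`` (when counts are
    given) and ``summary.json``/``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fai = config.fai or (config.fasta + ".fai")
    if not Path(fai).exists():
        Fasta(config.fasta)  # builds the index
    scaffold_lengths = read_scaffold_lengths(fai)

    matrix = variants.read_vcf(config.vcf, config.popmap)
    n_raw = matrix.n_sites
    matrix = variants.apply_hard_filters(matrix, config.hard_filters)
    n_hard = matrix.n_sites
    matrix = variants.mask_low_depth(matrix, min_dp=config.min_dp)
    n_masked = matrix.n_sites

    gw_fst = fstscan.genome_wide_fst(matrix)
    logger.info("genome-wide FST = %.5f", gw_fst)

    windows = fstscan.windowed_fst(
        matrix,
        scaffold_lengths,
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        min_scaffold_bp=config.min_scaffold_bp,
    )
    scan = fstscan.top_quantile(windows, q=config.top_frac)
    _write_tsv(fstscan.windows_to_frame(windows), outdir / "windows.tsv")
    with open(outdir / "selected_windows.bed", "w") as fh:
        for w in sorted(scan.selected, key=lambda w: (w.scaffold, w.start)):
            fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\n")

    counts = variants.allele_counts(matrix)
    snvs = hdr_mod.find_diverged_snvs(counts, min_called=config.min_called)
    _write_tsv(
        pd.DataFrame(
            [
                (s.scaffold, s.pos, s.ref, s.alt, s.fixed_pop, s.fixed_allele,
                 s.other_pop_het_count)
                for s in snvs
            ],
            columns=["scaffold", "pos", "ref", "alt", "fixed_pop", "fixed_allele",
                     "other_pop_het_count"],
        ),
        outdir / "diverged_snvs.tsv",
    )

    hdr_windows = hdr_mod.select_hdr_windows(scan, snvs)
    hdrs = hdr_mod.merge_windows(hdr_windows, snvs)
    hdr_mod.write_hdrs(hdrs, outdir / "hdrs.bed", outdir / "hdrs.tsv")

    summary = {
        "genome_wide_fst": gw_fst,
        "n_sites_raw": n_raw,
        "n_sites_after_hard_filters": n_hard,
        "n_sites_after_depth_mask": n_masked,
        "n_windows": len(windows),
        "fst_threshold": scan.threshold,
        "n_selected_windows": len(scan.selected),
        "n_diverged_snvs": len(snvs),
        "n_hdr_windows": len(hdr_windows),
        "n_hdrs": len(hdrs),
    }

    candidates = []
    if config.gff3:
        gene_models = genes_mod.read_gff(config.gff3)
        reference = Fasta(config.fasta)
        candidates = genes_mod.candidate_genes(
            gene_models, hdrs, snvs, cds_only=config.cds_only_candidates
        )
        overlap = genes_mod.genes_in_hdrs(gene_models, hdrs)
        _write_tsv(
            pd.DataFrame(
                [
                    (c.gene.gene_id, c.gene.transcript_id, c.gene.scaffold,
                     c.gene.start, c.gene.end, len(c.diverged_snvs))
                    for c in candidates
                ],
                columns=["gene_id", "transcript_id", "scaffold", "start", "end",
                         "n_diverged_snvs"],
            ),
            outdir / "candidate_genes.tsv",
        )
        aa_rows = []
        for cand in candidates:
            for snv in cand.diverged_snvs:
                result = effects.annotate_snv(snv, cand.gene, reference)
                if isinstance(result, effects.AminoAcidChange):
                    aa_rows.append(
                        (result.gene_id, result.transcript_id, snv.scaffold, snv.pos,
                         f"{result.cds_pos} {snv.ref} > {snv.alt}", result.ref_codon,
                         result.alt_codon, result.label, result.synonymous)
                    )
        _write_tsv(
            pd.DataFrame(
                aa_rows,
                columns=["gene_id", "transcript_id", "scaffold", "pos", "cds_change",
                         "ref_codon", "alt_codon", "aa_change", "synonymous"],
            ),
            outdir / "amino_acid_changes.tsv",
        )
        summary["n_genes_in_hdrs"] = len(
            {g.gene_id for glist in overlap.values() for g in glist}
        )
        summary["n_candidate_genes"] = len({c.gene.gene_id for c in candidates})
        summary["n_amino_acid_changes"] = len(aa_rows)
        summary["n_nonsynonymous_changes"] = sum(1 for r in aa_rows if not r[8])

    if config.counts and config.lengths:
        count_tab = pd.read_csv(config.counts, sep="\t", index_col=0)
        length_tab = pd.read_csv(config.lengths, sep="\t", index_col=0)["length"]
        tpm = expression.compute_tpm(count_tab, length_tab)
        pct = expression.percentile_rank(tpm, config.expressed_min_tpm)
        report = expression.expression_report(tpm, pct, config.tpm_rank_cutoff)
        _write_tsv(report, outdir / "expression_ranks.tsv")
        flags = expression.high_expression_screen(pct, config.tpm_rank_cutoff)
        summary["n_genes_expressed_screen"] = int(flags.sum())
        if candidates:
            cand_ids = {c.gene.gene_id for c in candidates}
            summary["n_candidates_highly_expressed"] = int(
                flags.reindex(sorted(cand_ids)).fillna(False).sum()
            )

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    params = {}
    for k, v in dataclasses.asdict(config).items():
        if k == "outdir":
            continue
        # record input files by basename so a relocated but otherwise
        # identical run yields byte-identical outputs
        if k in ("vcf", "fasta", "popmap", "gff3", "counts", "lengths", "fai"):
            params[k] = None if v is None else Path(v).name
        else:
            params[k] = v
    manifest = {"parameters": params, "summary": summary}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
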