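"""Gene models from GFF3, gene/HDR intersection, the candidate-gene rule, and
filtering of tabular homology hits.

A *candidate gene* is a gene whose span contains at least one diverged SNV
lying inside an HDR.  The span is the full gene region including introns and
UTRs by default; ``cds_only=True`` restricts containment to CDS segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CdsSegment:
    start: int  # 0-based half-open
    end: int
    phase: int


@dataclass
class GeneModel:
    """One transcript's gene structure in 0-based half-open coordinates."""

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds_segments: list = field(default_factory=list)
    phase_ok: bool = True

    @property
    def cds_length(self) -> int:
        total = sum(seg.end - seg.start for seg in self.cds_segments)
        first = self.transcription_order()[0].phase if self.cds_segments else 0
        return total - first

    def transcription_order(self) -> list:
        """CDS segments in the order they are transcribed."""
        segs = sorted(self.cds_segments, key=lambda s: s.start)
        return segs if self.strand == "+" else segs[::-1]

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_cds(self, pos0: int) -> bool:
        return any(seg.start <= pos0 < seg.end for seg in self.cds_segments)


def read_gff(path) -> list:
    """Parse a GFF3 file into :class:`GeneModel` records (one per transcript).

    1-based inclusive GFF coordinates become 0-based half-open.  Transcripts
    whose CDS length is not a codon multiple after phase adjustment are kept
    but flagged (``phase_ok=False``) with a warning; an mRNA without a parent
    gene is an error.
    """
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # header-only GFF3: valid, no models
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise ValueError(f"mRNA {mrna.id} has no parent gene")
        gene = parents[0]
        exons = sorted(
            ((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")),
        )
        cds = sorted(
            (
                CdsSegment(f.start - 1, f.end, int(f.frame) if f.frame != "." else 0)
                for f in db.children(mrna, featuretype="CDS")
            ),
            key=lambda s: s.start,
        )
        model = GeneModel(
            gene_id=gene.id,
            transcript_id=mrna.id,
            scaffold=mrna.seqid,
            strand=mrna.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=list(exons),
            cds_segments=cds,
        )
        if cds and model.cds_length % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not a codon multiple", mrna.id, model.cds_length
            )
            model.phase_ok = False
        models.append(model)
    return models


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def genes_in_hdrs(genes: list, hdrs: list) -> dict:
    """Map each HDR (keyed by ``(scaffold, start, end)``) to genes whose span
    intersects it by >= 1 bp.  Book-ended gene/HDR pairs do not overlap."""
    out = {}
    for h in hdrs:
        out[h.key] = [
            g
            for g in genes
            if g.scaffold == h.scaffold and _overlaps(g.start, g.end, h.start, h.end)
        ]
    return out


@dataclass
class CandidateGene:
    gene: GeneModel
    diverged_snvs: list


def candidate_genes(genes: list, hdrs: list, snvs: list, cds_only: bool = False) -> list:
    """Apply the candidate-gene rule: a gene qualifies iff it contains >= 1
    diverged SNV that itself lies inside an HDR."""
    in_hdr = []
    for s in snvs:
        if any(h.scaffold == s.scaffold and h.start <= s.pos0 < h.end for h in hdrs):
            in_hdr.append(s)
    out = []
    for g in genes:
        hits = [
            s
            for s in in_hdr
            if s.scaffold == g.scaffold
            and (g.in_cds(s.pos0) if cds_only else g.contains(s.pos0))
        ]
        if hits:
            out.append(CandidateGene(gene=g, diverged_snvs=hits))
    return out


#: Standard 12-column tabular alignment-hit layout (BLAST outfmt 6).
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


def read_homology_hits(path) -> pd.DataFrame:
    """Read tabular homology hits (12-column outfmt-6-style TSV)."""
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")


def filter_homology_hits(
    hits: pd.DataFrame, max_e: float = 1e-30, min_identity: float = 90.0
) -> pd.DataFrame:
    """Per query, keep the best-bit-score hit iff it passes both thresholds
    (e-value <= ``max_e`` and identity >= ``min_identity``).

    Only the top hit per query is ever considered: a weaker hit cannot rescue
    a query whose best hit fails.
    """
    if hits.empty:
        return hits.copy()
    best = hits.loc[hits.groupby("query_id")["bit_score"].idxmax()]
    keep = (best["e_value"] <= max_e) & (best["percent_identity"] >= min_identity)
    return best[keep].reset_index(drop=True)
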