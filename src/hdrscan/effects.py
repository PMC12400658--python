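"""Codon-level consequences of diverged SNVs, per-sample consensus coding
sequences, and pairwise sequence divergence.

The annotation maps a genomic SNV into the spliced, strand-oriented CDS of a
transcript, mutates the affected codon and translates both alleles with the
standard genetic code.  Consensus CDSs substitute a sample's genotypes into
the reference CDS (heterozygotes become IUPAC ambiguity codes) and pairwise
divergence is the p-distance with pairwise deletion of ambiguous sites, the
classic distance for near-identical coding sequences; a Jukes-Cantor
correction is available for completeness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .genes import GeneModel
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)

IUPAC_HET = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

_COMPLEMENT = str.maketrans("ACGTMRWSYKN", "TGCAKYWSRMN")


def _fetch(reference, scaffold: str, start0: int, end0: int) -> str:
    """Slice ``[start0, end0)`` out of a reference provided as a mapping of
    strings, numpy byte arrays, or a pyfaidx.Fasta."""
    seq = reference[scaffold]
    if isinstance(seq, str):
        return seq[start0:end0]
    if isinstance(seq, np.ndarray):
        return seq[start0:end0].tobytes().decode()
    return str(seq[start0:end0])  # pyfaidx FastaRecord slice


def _scaffold_length(reference, scaffold: str) -> int:
    seq = reference[scaffold]
    return len(seq)


@dataclass
class CdsSequence:
    """A spliced, strand-oriented coding sequence."""

    transcript_id: str
    sequence: str
    source: str = "reference"

    def __post_init__(self):
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.sequence)} not a codon multiple"
            )

    def translate(self) -> str:
        return str(Seq(self.sequence).translate())


@dataclass(frozen=True)
class AminoAcidChange:
    """Codon-level consequence of one SNV on one transcript."""

    gene_id: str
    transcript_id: str
    cds_pos: int  # 1-based position in the spliced CDS
    codon_index: int  # 1-based
    codon_pos: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def label(self) -> str:
        """Compact protein-level label, e.g. ``Pro747Ser``."""
        three = {
            "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
            "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
            "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
            "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
            "*": "Ter", "X": "Xaa",
        }
        return f"{three[self.ref_aa]}{self.codon_index}{three[self.alt_aa]}"


def cds_coordinates(gene: GeneModel) -> list:
    """Genomic 0-based positions of the spliced CDS in transcription order,
    with the first segment's phase trimmed off the front."""
    coords = []
    for seg in gene.transcription_order():
        span = range(seg.start, seg.end)
        coords.extend(span if gene.strand == "+" else reversed(span))
    first_phase = gene.transcription_order()[0].phase if gene.cds_segments else 0
    return coords[first_phase:]


def spliced_cds(gene: GeneModel, reference) -> CdsSequence:
    """Extract the spliced, strand-oriented CDS from the reference.

    Minus-strand genes are reverse-complemented; the phase of the first
    transcribed segment is trimmed so translation starts at a codon boundary.
    """
    length = _scaffold_length(reference, gene.scaffold)
    for seg in gene.cds_segments:
        if seg.start < 0 or seg.end > length:
            raise ValueError(
                f"{gene.transcript_id}: CDS segment [{seg.start},{seg.end}) outside "
                f"scaffold {gene.scaffold} (length {length})"
            )
    parts = []
    for seg in sorted(gene.cds_segments, key=lambda s: s.start):
        parts.append(_fetch(reference, gene.scaffold, seg.start, seg.end))
    genomic = "".join(parts)
    seq = genomic if gene.strand == "+" else genomic.translate(_COMPLEMENT)[::-1]
    first_phase = gene.transcription_order()[0].phase if gene.cds_segments else 0
    return CdsSequence(gene.transcript_id, seq[first_phase:], source="reference")

NONCODING = "noncoding"
SPLICE_REGION = "splice_region"


def annotate_snv(snv, gene: GeneModel, reference, splice_margin: int = 2):
    """Annotate one SNV against one transcript.

    Returns an :class:`AminoAcidChange` when the SNV falls in the spliced
    CDS; the string ``"splice_region"`` when it falls within
    ``splice_margin`` bp of a CDS segment boundary on the intronic side; and
    ``"noncoding"`` anywhere else inside the gene span.  ``snv`` needs
    ``scaffold``/``pos``/``ref``/``alt`` attributes (1-based position).

    The reference base at the site must equal ``snv.ref`` — a mismatch means
    a coordinate or assembly inconsistency and raises.
    """
    if snv.scaffold != gene.scaffold:
        raise ValueError(
            f"SNV on {snv.scaffold} annotated against gene on {gene.scaffold}"
        )
    pos0 = snv.pos - 1
    genome_base = _fetch(reference, gene.scaffold, pos0, pos0 + 1).upper()
    if genome_base != snv.ref:
        raise ValueError(
            f"REF mismatch at {snv.scaffold}:{snv.pos}: VCF says {snv.ref}, "
            f"reference has {genome_base}"
        )

    coords = cds_coordinates(gene)
    try:
        idx = coords.index(pos0)
    except ValueError:
        if any(
            0 < (seg.start - pos0) <= splice_margin or 0 < (pos0 - (seg.end - 1)) <= splice_margin
            for seg in gene.cds_segments
        ):
            return SPLICE_REGION
        return NONCODING

    cds = spliced_cds(gene, reference).sequence
    cds_pos = idx + 1
    codon_index = (cds_pos - 1) // 3 + 1
    codon_pos = (cds_pos - 1) % 3 + 1
    if codon_index * 3 > len(cds):  # trailing partial codon (phase-trimmed models)
        return NONCODING
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]

    ref_base = snv.ref if gene.strand == "+" else snv.ref.translate(_COMPLEMENT)
    alt_base = snv.alt if gene.strand == "+" else snv.alt.translate(_COMPLEMENT)
    assert ref_codon[codon_pos - 1] == ref_base
    alt_codon = ref_codon[: codon_pos - 1] + alt_base + ref_codon[codon_pos:]
    return AminoAcidChange(
        gene_id=gene.gene_id,
        transcript_id=gene.transcript_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=str(Seq(ref_codon).translate()),
        alt_aa=str(Seq(alt_codon).translate()),
    )


def consensus_cds(
    gene: GeneModel, reference, matrix: GenotypeMatrix, sample_id: str
) -> CdsSequence:
    """Reference CDS with one sample's genotypes substituted in.

    Hom-ALT sites get the ALT base, heterozygotes the IUPAC two-base code,
    missing genotypes keep the reference base (counted in the log).  With an
    all-reference genotype vector the result equals the reference CDS.
    """
    if sample_id not in matrix.samples:
        raise ValueError(f"unknown sample: {sample_id}")
    col = matrix.samples.index(sample_id)

    edits = {}  # genomic pos0 -> substituted forward-strand base
    n_missing = 0
    sites = matrix.sites
    on_scaf = sites.index[sites["scaffold"] == gene.scaffold]
    for i in on_scaf:
        pos0 = int(sites.at[i, "pos"]) - 1
        if not gene.in_cds(pos0):
            continue
        dos = int(matrix.dosage[i, col])
        ref, alt = sites.at[i, "ref"], sites.at[i, "alt"]
        if dos == 2:
            edits[pos0] = alt
        elif dos == 1:
            edits[pos0] = IUPAC_HET[frozenset((ref, alt))]
        elif dos < 0:
            n_missing += 1
    if n_missing:
        logger.info(
            "consensus_cds %s/%s: %d missing genotype(s) kept as reference",
            gene.transcript_id,
            sample_id,
            n_missing,
        )

    bases = []
    for pos0 in cds_coordinates(gene):
        base = edits.get(pos0) or _fetch(reference, gene.scaffold, pos0, pos0 + 1)
        if gene.strand == "-":
            base = base.translate(_COMPLEMENT)
        bases.append(base)
    return CdsSequence(gene.transcript_id, "".join(bases), source=f"consensus:{sample_id}")


def p_distance(seq1: str, seq2: str) -> float:
    """Proportion of differing sites over comparable sites (pairwise deletion).

    Sites where either base is not an unambiguous A/C/G/T are excluded.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence lengths differ: {len(seq1)} vs {len(seq2)}")
    comparable = diffs = 0
    for x, y in zip(seq1.upper(), seq2.upper()):
        if x in "ACGT" and y in "ACGT":
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable sites")
    return diffs / comparable


def divergence(seq1: str, seq2: str, model: str = "p") -> float:
    """Pairwise divergence: ``model="p"`` (p-distance, default) or ``"jc"``
    (Jukes-Cantor correction)."""
    p = p_distance(seq1, seq2)
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            raise ValueError("Jukes-Cantor undefined for p >= 0.75")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise ValueError(f"unknown model: {model}")
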