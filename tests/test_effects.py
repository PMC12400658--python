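"""Codon-level annotation, consensus CDS construction and p-distance,
validated against whole-CDS mutate-and-translate oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from hdrscan.effects import (
    NONCODING,
    SPLICE_REGION,
    AminoAcidChange,
    annotate_snv,
    consensus_cds,
    divergence,
    p_distance,
    spliced_cds,
)
from hdrscan.genes import CdsSegment, GeneModel
from hdrscan.variants import MISSING

from oracles import make_matrix, mutate_and_translate, naive_spliced_cds


def _gene(scaffold, strand, segments, gene_id="g1"):
    segs = [CdsSegment(*s) for s in segments]
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        scaffold=scaffold,
        strand=strand,
        start=min(s.start for s in segs),
        end=max(s.end for s in segs),
        exons=[(s.start, s.end) for s in segs],
        cds_segments=segs,
    )


def _snv(scaffold, pos, ref, alt):
    return SimpleNamespace(scaffold=scaffold, pos=pos, ref=ref, alt=alt)


def test_spliced_plus_strand_single_segment_identity():
    ref = {"s1": "ATGAAATGA"}
    gene = _gene("s1", "+", [(0, 9, 0)])
    assert spliced_cds(gene, ref).sequence == "ATGAAATGA"


def test_spliced_minus_strand_reverse_complement():
    ref = {"s1": "TCACAT"}
    gene = _gene("s1", "-", [(0, 6, 0)])
    assert spliced_cds(gene, ref).sequence == "ATGTGA"


def test_spliced_multi_segment_matches_naive_oracle():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    ref = {"s1": seq}
    for strand in "+-":
        gene = _gene("s1", strand, [(10, 100, 0), (150, 240, 0), (300, 345, 0)])
        assert spliced_cds(gene, ref).sequence == naive_spliced_cds(gene, ref)


def test_spliced_out_of_bounds_segment_errors():
    gene = _gene("s1", "+", [(0, 30, 0)])
    with pytest.raises(ValueError, match="outside"):
        spliced_cds(gene, {"s1": "ATG"})


def test_pro747ser_codon_position_one_transition():
    """A C>T at spliced-CDS position 2239 in a CCT codon is a Pro747Ser
    change at codon position 1."""
    cds = "ATG" + "GCT" * 745 + "CCT" + "GCT" * 52 + "TAA"
    assert len(cds) == 2400
    ref = {"s1": "A" * 100 + cds + "A" * 50}
    gene = _gene("s1", "+", [(100, 2500, 0)])
    snv = _snv("s1", 100 + 2239, "C", "T")
    change = annotate_snv(snv, gene, ref)
    assert isinstance(change, AminoAcidChange)
    assert (change.cds_pos, change.codon_index, change.codon_pos) == (2239, 747, 1)
    assert (change.ref_codon, change.alt_codon) == ("CCT", "TCT")
    assert (change.ref_aa, change.alt_aa) == ("P", "S")
    assert change.label == "Pro747Ser"
    assert not change.synonymous


def test_third_position_synonymous_change():
    ref = {"s1": "ATGGCTTAA"}
    gene = _gene("s1", "+", [(0, 9, 0)])
    change = annotate_snv(_snv("s1", 6, "T", "C"), gene, ref)  # GCT -> GCC
    assert change.synonymous
    assert (change.ref_aa, change.alt_aa) == ("A", "A")
    assert change.codon_pos == 3


def test_intronic_and_splice_region_classification():
    seq = "ATGAAA" + "GTTTTTAG" + "GGGTAA"  # exon1, intron, exon2
    ref = {"s1": seq}
    gene = _gene("s1", "+", [(0, 6, 0), (14, 20, 0)])
    assert annotate_snv(_snv("s1", 7, "G", "A"), gene, ref) == SPLICE_REGION
    assert annotate_snv(_snv("s1", 10, "T", "A"), gene, ref) == NONCODING


def test_reference_mismatch_raises():
    ref = {"s1": "ATGAAATGA"}
    gene = _gene("s1", "+", [(0, 9, 0)])
    with pytest.raises(ValueError, match="REF mismatch"):
        annotate_snv(_snv("s1", 2, "C", "G"), gene, ref)


def test_annotation_equals_mutation_oracle_on_simulated_genes(sim_dataset):
    """200 random CDS SNVs across the simulated gene set (both strands,
    multi-exon): codon annotation must equal the mutate-whole-genome,
    re-splice, re-translate oracle."""
    rng = np.random.default_rng(17)
    refdict = {k: v.tobytes().decode() for k, v in sim_dataset.reference.items()}
    cases = 0
    while cases < 200:
        gene = sim_dataset.genes[int(rng.integers(len(sim_dataset.genes)))]
        seg = gene.cds_segments[int(rng.integers(len(gene.cds_segments)))]
        pos0 = int(rng.integers(seg.start, seg.end))
        ref_base = refdict[gene.scaffold][pos0]
        alt_base = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
        change = annotate_snv(
            _snv(gene.scaffold, pos0 + 1, ref_base, alt_base),
            gene,
            sim_dataset.reference,
        )
        assert isinstance(change, AminoAcidChange)
        prot_ref, prot_alt, cds_ref, cds_alt = mutate_and_translate(
            gene, refdict, pos0 + 1, alt_base
        )
        assert cds_ref[change.cds_pos - 1] != cds_alt[change.cds_pos - 1]
        assert cds_alt == cds_ref[: change.cds_pos - 1] + cds_alt[change.cds_pos - 1] + cds_ref[change.cds_pos :]
        assert prot_ref[change.codon_index - 1] == change.ref_aa
        assert prot_alt[change.codon_index - 1] == change.alt_aa
        assert prot_alt == prot_ref[: change.codon_index - 1] + change.alt_aa + prot_ref[change.codon_index :]
        cases += 1


def test_consensus_substitutions_and_iupac():
    ref = {"s1": "ATGGCTGCAGCTTAA"}
    gene = _gene("s1", "+", [(0, 15, 0)])
    # sites at pos 4 (1-based, base C) hom-ALT T; pos 7 (G) het G/A
    matrix = make_matrix([[2], [1]], [[2], [1]], positions=[4, 7])
    matrix.sites.loc[0, ["ref", "alt"]] = ["G", "T"]
    matrix.sites.loc[1, ["ref", "alt"]] = ["G", "A"]
    out = consensus_cds(gene, ref, matrix, "A0")
    assert out.sequence == "ATGTCTRCAGCTTAA"


def test_consensus_minus_strand_complements_ambiguity():
    ref = {"s1": "TTACATCCCAGCCAT"}  # revcomp -> ATGGCTGGGATGTAA
    gene = _gene("s1", "-", [(0, 15, 0)])
    matrix = make_matrix([[1]], [[1]], positions=[5])  # forward het A/G at pos0 4
    matrix.sites.loc[0, ["ref", "alt"]] = ["A", "G"]
    out = consensus_cds(gene, ref, matrix, "A0")
    # forward R (A/G) complements to Y (C/T) on the coding strand
    assert out.sequence == "ATGGCTGGGAYGTAA"


def test_consensus_all_reference_is_identity():
    ref = {"s1": "ATGGCTGCATAA"}
    gene = _gene("s1", "+", [(0, 12, 0)])
    matrix = make_matrix([[0], [MISSING]], [[0], [0]], positions=[4, 7])
    out = consensus_cds(gene, ref, matrix, "A0")
    assert out.sequence == spliced_cds(gene, ref).sequence


def test_p_distance_basics():
    assert p_distance("ATGC", "ATGC") == 0.0
    assert p_distance("ATGC", "ATGA") == 0.25
    assert p_distance("ATGC", "ATGC") == p_distance("ATGC", "ATGC")


def test_p_distance_counts_k_over_L():
    rng = np.random.default_rng(4)
    L, k = 2895, 13
    seq = "".join(rng.choice(list("ACGT"), size=L))
    mutated = list(seq)
    for i in rng.choice(L, size=k, replace=False):
        mutated[i] = "ACGT".replace(seq[i], "")[0]
    assert p_distance(seq, "".join(mutated)) == k / L
    assert p_distance(seq, "".join(mutated)) == pytest.approx(0.00449, abs=2e-4)


def test_p_distance_pairwise_deletion_of_ambiguity():
    assert p_distance("AYGC", "ATGA") == pytest.approx(1 / 3)
    assert p_distance("ANGC", "AYGC") == pytest.approx(0.0)


def test_p_distance_error_cases():
    with pytest.raises(ValueError, match="lengths"):
        p_distance("ATG", "AT")
    with pytest.raises(ValueError, match="comparable"):
        p_distance("NNN", "ATG")


def test_jukes_cantor_option():
    p = p_distance("ATGC", "ATGA")
    assert divergence("ATGC", "ATGA", model="jc") == pytest.approx(
        -0.75 * np.log(1 - 4 * p / 3)
    )
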