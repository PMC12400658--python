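"""The generator must hit its design targets: deterministic output, planted
sites that satisfy the diverged-SNV criterion by construction, background
differentiation near the configured F, and files that parse strictly."""

import numpy as np
import pandas as pd
import pytest
from cyvcf2 import VCF
from pyfaidx import Fasta

from hdrscan import fstscan, genes as genes_mod, variants
from hdrscan.effects import spliced_cds
from hdrscan.simdata import (
    PlantedRegion,
    SimConfig,
    simulate_dataset,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
    simulate_reference,
    write_fasta,
)

from oracles import satisfies_diverged_criterion, wc_fst_over_sites


def test_reference_lengths_and_determinism(tmp_path):
    cfg = SimConfig(seed=7, scaffold_lengths={"s1": 12345, "s2": 8000}, gene_count=0)
    ref = simulate_reference(cfg)
    assert {k: len(v) for k, v in ref.items()} == {"s1": 12345, "s2": 8000}
    seq = ref["s1"].tobytes().decode()
    assert set(seq) <= set("ACGT")

    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_fasta(ref, p1, make_index=False)
    write_fasta(simulate_reference(cfg), p2, make_index=False)
    assert p1.read_bytes() == p2.read_bytes()


def test_reference_rejects_nonpositive_length():
    with pytest.raises(ValueError, match="non-positive"):
        simulate_reference(SimConfig(scaffold_lengths={"s1": 0}))


def test_snv_density_too_high_is_an_error():
    cfg = SimConfig(scaffold_lengths={"s1": 100}, snv_density=2.0, gene_count=0)
    ref = simulate_reference(cfg)
    with pytest.raises(ValueError, match="density"):
        simulate_genotypes(cfg, ref)


@pytest.mark.parametrize(
    "mode,n_a,het_fraction,expected_hets",
    [("fixed_difference", 11, 0.2, 0), ("fixed_with_het", 10, 0.2, 2)],
)
def test_planted_modes_by_construction(mode, n_a, het_fraction, expected_hets):
    cfg = SimConfig(
        seed=3,
        scaffold_lengths={"s1": 3000},
        n_popA=n_a,
        planted_regions=[PlantedRegion("s1", 1000, 1001, mode)],
        het_fraction_other_pop=het_fraction,
        missing_rate=0.0,
        gene_count=0,
    )
    matrix, truth = simulate_genotypes(cfg, simulate_reference(cfg))
    (i,) = matrix.sites.index[matrix.sites["pos"] == 1001]
    row = matrix.dosage[i]
    pop_a, pop_b = row[:n_a], row[n_a:]
    assert (pop_b == 2).all()
    assert (pop_a != 2).all()
    assert (pop_a == 1).sum() == expected_hets
    assert len(truth.planted_sites) == 1


def test_background_fst_recovers_configured_F():
    """Genome-wide WC FST of ~20k Balding-Nichols sites, checked against an
    independent longhand summation, lands within ±0.03 of F=0.10."""
    cfg = SimConfig(
        seed=5,
        scaffold_lengths={"s1": 4_000_000},
        gene_count=0,
        info_fail_fraction=0.0,
    )
    matrix, _ = simulate_genotypes(cfg, simulate_reference(cfg))
    assert matrix.n_sites >= 19_000
    est = fstscan.genome_wide_fst(matrix)
    assert abs(est - 0.10) < 0.03
    sub = np.arange(0, matrix.n_sites, 10)  # oracle is O(sites), keep it light
    oracle = wc_fst_over_sites(matrix, sub)
    est_sub = fstscan.genome_wide_fst(matrix.take_sites(sub))
    assert est_sub == pytest.approx(oracle, abs=1e-12)


def test_vcf_roundtrip_recovers_dosage(sim_dataset):
    m0 = sim_dataset.matrix
    m1 = variants.read_vcf(sim_dataset.paths["vcf"], sim_dataset.paths["popmap"])
    assert m1.samples == m0.samples
    assert np.array_equal(m1.dosage, m0.dosage)
    assert np.array_equal(m1.dp, m0.dp)
    pd.testing.assert_frame_equal(
        m1.sites[["scaffold", "pos", "ref", "alt"]],
        m0.sites[["scaffold", "pos", "ref", "alt"]],
    )


def test_emitted_files_parse_strictly(sim_dataset):
    fasta = Fasta(sim_dataset.paths["fasta"])
    assert {k: len(fasta[k]) for k in fasta.keys()} == sim_dataset.config.scaffold_lengths
    n_vcf = sum(1 for _ in VCF(sim_dataset.paths["vcf"]))
    assert n_vcf == sim_dataset.matrix.n_sites
    models = genes_mod.read_gff(sim_dataset.paths["gff3"])
    assert len(models) == len(sim_dataset.genes)
    counts = pd.read_csv(sim_dataset.paths["counts"], sep="\t", index_col=0)
    assert counts.shape == (len(sim_dataset.genes), 4)
    assert (counts.to_numpy() >= 0).all()


def test_gene_models_translate_cleanly(sim_dataset):
    """CDS lengths are codon multiples and reference translation carries no
    internal stop; the gene set spans both strands and includes multi-exon
    models."""
    strands, exon_counts = set(), set()
    for gene in sim_dataset.genes:
        assert gene.cds_length % 3 == 0
        protein = spliced_cds(gene, sim_dataset.reference).translate()
        assert protein[0] == "M"
        assert protein[-1] == "*"
        assert "*" not in protein[:-1]
        strands.add(gene.strand)
        exon_counts.add(len(gene.cds_segments))
    assert strands == {"+", "-"}
    assert max(exon_counts) >= 2


def test_gff_roundtrip_identical_models(sim_dataset):
    models = {m.transcript_id: m for m in genes_mod.read_gff(sim_dataset.paths["gff3"])}
    for gene in sim_dataset.genes:
        got = models[gene.transcript_id]
        assert (got.scaffold, got.strand, got.start, got.end) == (
            gene.scaffold, gene.strand, gene.start, gene.end,
        )
        assert got.exons == gene.exons
        assert got.cds_segments == gene.cds_segments


def test_zero_genes_give_empty_but_valid_gff(tmp_path):
    cfg = SimConfig(seed=1, gene_count=0)
    data = simulate_dataset(cfg, tmp_path)
    assert genes_mod.read_gff(data.paths["gff3"]) == []


def test_planted_sites_pass_diverged_criterion(sim_dataset):
    """Every planted site satisfies the fixation rule on realized genotypes."""
    matrix = sim_dataset.matrix
    n_a = sim_dataset.config.n_popA
    for _, site in sim_dataset.truth.planted_sites.iterrows():
        (i,) = matrix.sites.index[
            (matrix.sites["scaffold"] == site["scaffold"])
            & (matrix.sites["pos"] == site["pos"])
        ]
        row = matrix.dosage[i]
        assert satisfies_diverged_criterion(list(row[:n_a]), list(row[n_a:]))


def test_truth_effect_matches_planted_example(sim_dataset):
    """Planted CDS SNVs in truth carry codon-consistent annotations."""
    eff = sim_dataset.truth.planted_effects
    assert len(eff) > 0
    assert ((eff["cds_pos"] - 1) // 3 + 1 == eff["codon_index"]).all()
    assert ((eff["cds_pos"] - 1) % 3 + 1 == eff["codon_pos"]).all()
    changed = eff["ref_codon"] != eff["alt_codon"]
    assert changed.all()


def test_failing_annotations_exceed_thresholds(sim_dataset):
    sites = sim_dataset.matrix.sites.set_index(["scaffold", "pos"])
    failing = sim_dataset.truth.failing_sites
    assert len(failing) > 0
    for _, row in failing.iterrows():
        val = sites.at[(row["scaffold"], row["pos"]), row["criterion"]]
        thr = variants.DEFAULT_HARD_FILTERS[row["criterion"]]
        if variants.FILTER_DIRECTIONS[row["criterion"]] == "lt":
            assert val < thr
        else:
            assert val > thr


def test_low_dp_fraction_present(sim_dataset):
    dp = sim_dataset.matrix.dp
    frac = (dp <= 3).mean()
    assert 0.005 < frac < 0.05  # around the configured 2%


def test_expression_deterministic_and_shaped(sim_dataset):
    counts, lengths = simulate_expression(sim_dataset.genes, 4, sim_dataset.config)
    counts2, _ = simulate_expression(sim_dataset.genes, 4, sim_dataset.config)
    pd.testing.assert_frame_equal(counts, counts2)
    assert counts.shape == (len(sim_dataset.genes), 4)
    assert (lengths > 0).all()
    assert counts.to_numpy().dtype.kind == "i"


def test_simulate_dataset_is_seed_deterministic(tmp_path):
    cfg = SimConfig(
        seed=9,
        scaffold_lengths={"s1": 30_000, "s2": 12_000},
        planted_regions=[PlantedRegion("s1", 8_000, 9_000)],
        gene_count=3,
    )
    d1 = simulate_dataset(cfg, tmp_path / "run1")
    d2 = simulate_dataset(cfg, tmp_path / "run2")
    for key in ("fasta", "vcf", "gff3", "counts", "popmap"):
        with open(d1.paths[key], "rb") as f1, open(d2.paths[key], "rb") as f2:
            assert f1.read() == f2.read(), key
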