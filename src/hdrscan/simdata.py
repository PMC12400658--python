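"""Synthetic two-population genomic datasets for exercising the divergence
scan end-to-end: reference FASTA, multi-sample VCF, GFF3 gene models,
expression count tables, and a truth table for every planted signal.

Background genotypes follow the Balding-Nichols model: an ancestral allele
frequency drawn uniformly on [0.05, 0.95], per-population frequencies drawn
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around it, and diploid genotypes
``Binomial(2, p_pop)`` — a stationary model whose differentiation is
controlled directly by ``background_F``.  Realized-monomorphic draws are
rejected and resampled so every emitted site is variable.

Planted regions carry the divergence signal the scan is meant to find:

* ``fixed_difference`` — population B homozygous ALT, population A
  homozygous REF at every planted site;
* ``fixed_with_het`` — population B homozygous ALT, a fixed fraction of
  population A heterozygous (never homozygous ALT), which still satisfies
  the diverged-SNV criterion.

Each generation stage draws from its own labeled child of the master seed,
so adding a stage never perturbs another stage's stream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from .genes import CdsSegment, GeneModel
from .variants import GenotypeMatrix, INFO_FIELDS, MISSING, SITE_COLUMNS

_STREAMS = {
    "reference": 1,
    "positions": 2,
    "alleles": 3,
    "frequencies": 4,
    "genotypes": 5,
    "missing": 6,
    "annotations": 7,
    "depth": 8,
    "genes": 9,
    "expression": 10,
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MODES = ("fixed_difference", "fixed_with_het")

STAGE_LABELS = ("pre_spawning", "setting", "spawning", "post_spawning")


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Labeled child stream of the master seed."""
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantedRegion:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    mode: str = "fixed_difference"


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the sampling design the scan targets: 11 vs 14 diploid
    colonies, background differentiation around 0.10, one SNV per ~200 bp,
    and a genome of several scaffolds including one at or below the 10 kb
    window-scan cutoff.
    """

    seed: int = 0
    scaffold_lengths: dict = field(
        default_factory=lambda: {
            "scaffold_1": 60_000,
            "scaffold_2": 40_000,
            "scaffold_3": 25_000,
            "scaffold_4": 8_000,
        }
    )
    n_popA: int = 11
    n_popB: int = 14
    background_F: float = 0.10
    snv_density: float = 1.0 / 200.0
    planted_regions: list = field(default_factory=list)
    het_fraction_other_pop: float = 0.2
    gene_count: int = 8
    missing_rate: float = 0.01
    dp_mean: float = 20.0
    low_dp_fraction: float = 0.02
    info_fail_fraction: float = 0.02
    info_missing_fraction: float = 0.10
    min_cds_codons: int = 100
    max_cds_codons: int = 400

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffold_lengths)

    @property
    def samples(self) -> list:
        return [f"A_{i + 1:02d}" for i in range(self.n_popA)] + [
            f"B_{i + 1:02d}" for i in range(self.n_popB)
        ]

    @property
    def populations(self) -> dict:
        return {s: s[0] for s in self.samples}

    def validate(self) -> None:
        for name, length in self.scaffold_lengths.items():
            if length <= 0:
                raise ValueError(f"scaffold {name}: non-positive length {length}")
        if not 0.0 < self.background_F < 1.0:
            raise ValueError("background_F must lie in (0, 1)")
        if not 0.0 <= self.het_fraction_other_pop < 1.0:
            raise ValueError("het_fraction_other_pop must lie in [0, 1)")
        for r in self.planted_regions:
            if r.scaffold not in self.scaffold_lengths:
                raise ValueError(f"planted region on unknown scaffold {r.scaffold}")
            if not 0 <= r.start < r.end <= self.scaffold_lengths[r.scaffold]:
                raise ValueError(f"planted region outside scaffold bounds: {r}")
            if r.mode not in MODES:
                raise ValueError(f"unknown planted mode: {r.mode}")


@dataclass
class TruthTable:
    """Ground truth for every planted signal, used as the test oracle."""

    planted_regions: list
    planted_sites: pd.DataFrame  # scaffold,pos,mode,ref,alt
    site_freqs: pd.DataFrame  # scaffold,pos,freq_A,freq_B
    failing_sites: pd.DataFrame  # scaffold,pos,criterion
    planted_effects: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "planted_regions": [dataclasses.asdict(r) for r in self.planted_regions],
            "planted_sites": self.planted_sites.to_dict(orient="list"),
            "site_freqs": self.site_freqs.to_dict(orient="list"),
            "failing_sites": self.failing_sites.to_dict(orient="list"),
            "planted_effects": None
            if self.planted_effects is None
            else self.planted_effects.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_regions=[PlantedRegion(**r) for r in payload["planted_regions"]],
            planted_sites=pd.DataFrame(payload["planted_sites"]),
            site_freqs=pd.DataFrame(payload["site_freqs"]),
            failing_sites=pd.DataFrame(payload["failing_sites"]),
            planted_effects=None
            if payload["planted_effects"] is None
            else pd.DataFrame(payload["planted_effects"]),
        )


# ---------------------------------------------------------------------------
# reference

def simulate_reference(config: SimConfig) -> dict:
    """Uniform-random A/C/G/T scaffolds of the configured lengths.

    Returns a dict of numpy byte arrays (dtype S1), mutable in place so gene
    models can recode their coding regions before genotypes are drawn.
    """
    config.validate()
    rng = child_rng(config.seed, "reference")
    return {
        name: _BASES[rng.integers(0, 4, size=length)]
        for name, length in config.scaffold_lengths.items()
    }


def write_fasta(reference: dict, path, width: int = 60, make_index: bool = True) -> None:
    """Write scaffolds as wrapped FASTA (and a .fai index alongside)."""
    with open(path, "w") as fh:
        for name, arr in reference.items():
            fh.write(f">{name}\n")
            seq = arr.tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    if make_index:
        Faidx(str(path), rebuild=True)


def read_scaffold_lengths(fai_path) -> dict:
    """Scaffold lengths from a samtools/pyfaidx .fai index."""
    lengths = {}
    with open(fai_path) as fh:
        for line in fh:
            parts = line.split("\t")
            lengths[parts[0]] = int(parts[1])
    return lengths


# ---------------------------------------------------------------------------
# gene models

def _split_lengths(total: int, parts: int, minimum: int, rng) -> list:
    """Split ``total`` into ``parts`` pieces each >= ``minimum``."""
    if total < parts * minimum:
        raise ValueError("CDS too short for requested exon count")
    extra = rng.multinomial(total - parts * minimum, [1.0 / parts] * parts)
    return [minimum + int(e) for e in extra]


def _random_coding_sequence(n_codons: int, rng) -> str:
    """ATG + random non-stop codons + a stop codon."""
    internal = rng.integers(0, len(_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_CODONS[i] for i in internal) + _STOPS[rng.integers(0, 3)]


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _place_interval(length: int, footprint: int, occupied: list, rng, tries: int = 200):
    for _ in range(tries):
        start = int(rng.integers(0, length - footprint + 1))
        end = start + footprint
        if all(end <= s or start >= e for s, e in occupied):
            return start
    return None


def simulate_gene_models(config: SimConfig, reference: dict) -> list:
    """Generate multi-exon gene models on both strands and recode the
    reference so each CDS translates without internal stop codons.

    The first genes are anchored over the configured planted regions (one
    each, while genes remain) so the candidate-gene and effect-annotation
    stages see positives; remaining genes are placed in unoccupied,
    unplanted sequence.  Mutates ``reference`` in place.
    """
    config.validate()
    rng = child_rng(config.seed, "genes")
    occupied = {name: [] for name in config.scaffold_lengths}
    for r in config.planted_regions:
        occupied[r.scaffold].append((r.start, r.end))

    genes = []
    for i in range(config.gene_count):
        strand = "+" if i % 2 == 0 else "-"
        n_exons = 1 + (i % 3)
        n_codons = int(rng.integers(config.min_cds_codons, config.max_cds_codons + 1))
        cds_len = 3 * n_codons
        exon_lens = _split_lengths(cds_len, n_exons, 30, rng)
        intron_lens = [int(x) for x in rng.integers(60, 301, size=n_exons - 1)]
        footprint = cds_len + sum(intron_lens)

        target = config.planted_regions[i] if i < len(config.planted_regions) else None
        if target is not None:
            scaffold = target.scaffold
            length = config.scaffold_lengths[scaffold]
            if footprint > length:
                raise ValueError(
                    f"gene footprint {footprint} exceeds scaffold {scaffold} ({length} bp)"
                )
            # anchor the gene over the planted region
            start = min(
                max(0, target.start - footprint // 3), length - footprint
            )
            taken = [
                iv for iv in occupied[scaffold] if iv != (target.start, target.end)
            ]
            if not all(start + footprint <= s or start >= e for s, e in taken):
                start = _place_interval(length, footprint, occupied[scaffold], rng)
                if start is None:
                    continue
        else:
            candidates = [
                n for n, L in config.scaffold_lengths.items() if L > footprint
            ]
            if not candidates:
                raise ValueError(f"gene footprint {footprint} exceeds every scaffold")
            scaffold = candidates[int(rng.integers(0, len(candidates)))]
            start = _place_interval(
                config.scaffold_lengths[scaffold], footprint, occupied[scaffold], rng
            )
            if start is None:
                continue
        occupied[scaffold].append((start, start + footprint))

        # genomic CDS segments
        segs = []
        cursor = start
        for k, ex_len in enumerate(exon_lens):
            segs.append((cursor, cursor + ex_len))
            cursor += ex_len
            if k < len(intron_lens):
                cursor += intron_lens[k]
        gene_end = segs[-1][1]

        # phases follow transcription order
        order = segs if strand == "+" else segs[::-1]
        phases = {}
        cum = 0
        for s, e in order:
            phases[(s, e)] = (3 - cum % 3) % 3
            cum += e - s

        coding = _random_coding_sequence(n_codons, rng)
        forward = coding if strand == "+" else _revcomp(coding)
        offset = 0
        arr = reference[scaffold]
        for s, e in segs:
            chunk = forward[offset : offset + (e - s)]
            arr[s:e] = np.frombuffer(chunk.encode(), dtype="S1")
            offset += e - s

        gid = f"gene_{i + 1:03d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                scaffold=scaffold,
                strand=strand,
                start=start,
                end=gene_end,
                exons=list(segs),
                cds_segments=[CdsSegment(s, e, phases[(s, e)]) for s, e in segs],
            )
        )
    return genes


def write_gff3(genes: list, scaffold_lengths: dict, path) -> None:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in scaffold_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
            cols = [g.scaffold, "hdrscan_sim"]
            fh.write(
                "\t".join(
                    cols + ["gene", str(g.start + 1), str(g.end), ".", g.strand, ".",
                            f"ID={g.gene_id}"]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    cols + ["mRNA", str(g.start + 1), str(g.end), ".", g.strand, ".",
                            f"ID={g.transcript_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        cols + ["exon", str(s + 1), str(e), ".", g.strand, ".",
                                f"ID={g.transcript_id}.exon{j};Parent={g.transcript_id}"]
                    )
                    + "\n"
                )
            for j, seg in enumerate(g.cds_segments, 1):
                fh.write(
                    "\t".join(
                        cols + ["CDS", str(seg.start + 1), str(seg.end), ".", g.strand,
                                str(seg.phase),
                                f"ID={g.transcript_id}.cds{j};Parent={g.transcript_id}"]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# genotypes

def _planted_positions(config: SimConfig) -> pd.DataFrame:
    spacing = max(1, round(1.0 / config.snv_density))
    rows = []
    for r in config.planted_regions:
        for pos0 in range(r.start, r.end, spacing):
            rows.append((r.scaffold, pos0, r.mode))
    return pd.DataFrame(rows, columns=["scaffold", "pos0", "mode"])


def simulate_genotypes(config: SimConfig, reference: dict):
    """Draw the genotype matrix and its truth table.

    Background sites follow Balding-Nichols at ``background_F``; planted
    sites inside the configured regions satisfy the diverged-SNV criterion
    by construction.  Per-genotype depth and site-level quality annotations
    are attached so the filtering stages have something to do; annotation
    failures are planted at background sites only, keeping the filter truth
    separable from the divergence truth.
    """
    config.validate()
    rng_pos = child_rng(config.seed, "positions")
    rng_alle = child_rng(config.seed, "alleles")
    rng_freq = child_rng(config.seed, "frequencies")
    rng_geno = child_rng(config.seed, "genotypes")
    rng_miss = child_rng(config.seed, "missing")
    rng_annot = child_rng(config.seed, "annotations")
    rng_dp = child_rng(config.seed, "depth")

    planted = _planted_positions(config)
    planted_keys = set(zip(planted["scaffold"], planted["pos0"]))

    rows = []  # scaffold, pos0, mode ('' = background)
    for name, length in config.scaffold_lengths.items():
        n_bg = int(round(config.snv_density * length))
        here_pos = np.array(
            sorted(p for s, p in planted_keys if s == name), dtype=np.int64
        )
        pool = np.setdiff1d(np.arange(length, dtype=np.int64), here_pos)
        if n_bg > len(pool):
            raise ValueError(
                f"snv_density too high: {n_bg} background sites requested on "
                f"{name} but only {len(pool)} free positions"
            )
        bg = np.sort(rng_pos.choice(pool, size=n_bg, replace=False))
        here = planted[planted["scaffold"] == name]
        mode_at = dict(zip(here["pos0"], here["mode"]))
        allpos = np.sort(np.concatenate([bg, here["pos0"].to_numpy(dtype=np.int64)]))
        for p in allpos:
            rows.append((name, int(p), mode_at.get(int(p), "")))

    scaffolds = [r[0] for r in rows]
    pos0 = np.array([r[1] for r in rows], dtype=np.int64)
    modes = np.array([r[2] for r in rows])
    S = len(rows)
    nA, nB = config.n_popA, config.n_popB
    n = nA + nB

    refs = np.array(
        [reference[sc][p].decode() for sc, p in zip(scaffolds, pos0)]
    )
    alt_choices = np.array(
        [
            "ACGT".replace(rb, "")[rng_alle.integers(0, 3)]
            for rb in refs
        ]
    )

    dosage = np.zeros((S, n), dtype=np.int8)
    freq_a = np.zeros(S)
    freq_b = np.zeros(S)

    is_bg = modes == ""
    bg_idx = np.flatnonzero(is_bg)
    F = config.background_F
    shape = (1.0 - F) / F
    todo = bg_idx
    while len(todo):
        p_anc = rng_freq.uniform(0.05, 0.95, size=len(todo))
        pA = rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pB = rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape)
        dA = rng_geno.binomial(2, pA[:, None], size=(len(todo), nA)).astype(np.int8)
        dB = rng_geno.binomial(2, pB[:, None], size=(len(todo), nB)).astype(np.int8)
        combined = np.hstack([dA, dB])
        dosage[todo, :] = combined
        freq_a[todo] = pA
        freq_b[todo] = pB
        mono = combined.min(axis=1) == combined.max(axis=1)
        todo = todo[mono]  # resample realized-monomorphic draws

    fd_idx = np.flatnonzero(modes == "fixed_difference")
    dosage[np.ix_(fd_idx, np.arange(nA))] = 0
    dosage[np.ix_(fd_idx, np.arange(nA, n))] = 2
    freq_a[fd_idx], freq_b[fd_idx] = 0.0, 1.0

    fh_idx = np.flatnonzero(modes == "fixed_with_het")
    n_het = int(round(config.het_fraction_other_pop * nA))
    for i in fh_idx:
        row = np.zeros(n, dtype=np.int8)
        hets = rng_geno.permutation(nA)[:n_het]
        row[hets] = 1
        row[nA:] = 2
        dosage[i] = row
    freq_a[fh_idx] = n_het / (2.0 * nA)
    freq_b[fh_idx] = 1.0

    if config.missing_rate > 0:
        miss = rng_miss.random((S, n)) < config.missing_rate
        dosage[miss] = MISSING

    # site-level quality annotations: mostly passing, a configurable
    # fraction of background sites failing exactly one criterion
    info = {
        "QD": rng_annot.uniform(15.0, 35.0, S),
        "FS": rng_annot.uniform(0.0, 10.0, S),
        "MQ": rng_annot.uniform(50.0, 60.0, S),
        "SOR": rng_annot.uniform(0.5, 2.0, S),
        "MQRankSum": np.clip(rng_annot.normal(0.0, 1.0, S), -3.0, None),
        "ReadPosRankSum": np.clip(rng_annot.normal(0.0, 1.0, S), -3.0, None),
    }
    fail_draw = rng_annot.random(S)
    fail_crit = rng_annot.integers(0, len(INFO_FIELDS), S)
    failing_rows = []
    fail_values = {
        "QD": lambda r: r.uniform(0.1, 1.9),
        "FS": lambda r: r.uniform(60.5, 120.0),
        "MQ": lambda r: r.uniform(10.0, 39.5),
        "SOR": lambda r: r.uniform(3.1, 6.0),
        "MQRankSum": lambda r: r.uniform(-20.0, -12.6),
        "ReadPosRankSum": lambda r: r.uniform(-15.0, -8.1),
    }
    for i in range(S):
        if is_bg[i] and fail_draw[i] < config.info_fail_fraction:
            key = INFO_FIELDS[fail_crit[i]]
            info[key][i] = fail_values[key](rng_annot)
            failing_rows.append((scaffolds[i], int(pos0[i]) + 1, key))
    # rank-sum annotations genuinely absent for a fraction of passing sites
    failing_set = {(s, p) for s, p, _ in failing_rows}
    absent = rng_annot.random(S) < config.info_missing_fraction
    for key in ("MQRankSum", "ReadPosRankSum"):
        for i in np.flatnonzero(absent):
            if (scaffolds[i], int(pos0[i]) + 1) not in failing_set:
                info[key][i] = np.nan

    base_dp = 4 + rng_dp.poisson(max(config.dp_mean - 4.0, 1.0), size=(S, n))
    low = rng_dp.random((S, n)) < config.low_dp_fraction
    dp = np.where(low, rng_dp.integers(0, 4, size=(S, n)), base_dp).astype(np.int32)

    sites = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "pos": pos0 + 1,
            "ref": refs,
            "alt": alt_choices,
            **{k: info[k] for k in INFO_FIELDS},
        },
        columns=list(SITE_COLUMNS),
    )
    matrix = GenotypeMatrix(
        sites=sites,
        dosage=dosage,
        dp=dp,
        samples=config.samples,
        populations=config.populations,
    )
    planted_mask = ~is_bg
    truth = TruthTable(
        planted_regions=list(config.planted_regions),
        planted_sites=pd.DataFrame(
            {
                "scaffold": np.array(scaffolds)[planted_mask],
                "pos": pos0[planted_mask] + 1,
                "mode": modes[planted_mask],
                "ref": refs[planted_mask],
                "alt": alt_choices[planted_mask],
            }
        ).reset_index(drop=True),
        site_freqs=pd.DataFrame(
            {"scaffold": scaffolds, "pos": pos0 + 1, "freq_A": freq_a, "freq_B": freq_b}
        ),
        failing_sites=pd.DataFrame(
            failing_rows, columns=["scaffold", "pos", "criterion"]
        ),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# VCF / popmap output

_VCF_HEADER_INFO = {
    "QD": "Variant Confidence/Quality by Depth",
    "FS": "Phred-scaled p-value using Fisher's exact test to detect strand bias",
    "MQ": "RMS Mapping Quality",
    "SOR": "Symmetric Odds Ratio of 2x2 contingency table to detect strand bias",
    "MQRankSum": "Z-score From Wilcoxon rank sum test of Alt vs. Ref read mapping qualities",
    "ReadPosRankSum": "Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias",
}

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_sim_vcf(matrix: GenotypeMatrix, path, scaffold_lengths: dict | None = None) -> None:
    """Serialize a genotype matrix as VCF 4.2 with GT:DP genotypes.

    Reading the file back through :func:`hdrscan.variants.read_vcf` recovers
    the dosage matrix exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hdrscan-simdata\n")
        if scaffold_lengths:
            for name, length in scaffold_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for key in INFO_FIELDS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{_VCF_HEADER_INFO[key]}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            info = ";".join(
                f"{k}={row[k]:.4f}" for k in INFO_FIELDS if pd.notna(row[k])
            )
            calls = []
            for j in range(matrix.n_samples):
                gt = _GT_STRINGS[int(matrix.dosage[i, j])]
                dp = "." if matrix.dp is None else str(int(matrix.dp[i, j]))
                calls.append(f"{gt}:{dp}")
            fh.write(
                f"{row['scaffold']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t"
                f"{info or '.'}\tGT:DP\t" + "\t".join(calls) + "\n"
            )


def write_popmap(populations: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genes: list, n_conditions: int, config: SimConfig, labels: list | None = None
):
    """Negative-binomial count table (genes x conditions) plus gene lengths.

    Gene baseline means are lognormal, with mild per-condition fold jitter —
    enough structure for the TPM/rank stages without modelling real dynamics.
    Four unlabeled conditions default to the spawning-stage layout; other
    widths get generic labels (pass ``labels`` for colony-by-month designs).
    """
    if not genes:
        raise ValueError("simulate_expression requires at least one gene")
    if labels is None:
        labels = (
            list(STAGE_LABELS)
            if n_conditions == 4
            else [f"condition_{i + 1}" for i in range(n_conditions)]
        )
    if len(labels) != n_conditions:
        raise ValueError("label count does not match n_conditions")
    rng = child_rng(config.seed, "expression")
    G = len(genes)
    baseline = rng.lognormal(mean=math.log(50.0), sigma=1.5, size=G)
    jitter = rng.lognormal(mean=0.0, sigma=0.2, size=(G, n_conditions))
    mu = baseline[:, None] * jitter
    r = 5.0
    counts = rng.negative_binomial(r, r / (r + mu))
    index = [g.gene_id for g in genes]
    lengths = pd.Series([g.cds_length for g in genes], index=index, name="length")
    return pd.DataFrame(counts, index=index, columns=labels), lengths


# ---------------------------------------------------------------------------
# truth effects + orchestration

def _truth_cds_effect(gene: GeneModel, reference: dict, pos0: int, ref: str, alt: str):
    """Direct codon-effect computation for the truth table: splice the CDS
    base by base, substitute, translate."""
    coords = []
    for seg in gene.transcription_order():
        rng_ = range(seg.start, seg.end)
        coords.extend(rng_ if gene.strand == "+" else reversed(rng_))
    first_phase = gene.transcription_order()[0].phase
    coords = coords[first_phase:]
    if pos0 not in coords:
        return None
    idx = coords.index(pos0)
    arr = reference[gene.scaffold]
    bases = []
    for p in coords:
        b = arr[p].decode()
        bases.append(b if gene.strand == "+" else _COMP[b])
    ref_b = ref if gene.strand == "+" else _COMP[ref]
    alt_b = alt if gene.strand == "+" else _COMP[alt]
    assert bases[idx] == ref_b
    cds_pos = idx + 1
    ci = (cds_pos - 1) // 3
    ref_codon = "".join(bases[ci * 3 : ci * 3 + 3])
    mutated = list(bases)
    mutated[idx] = alt_b
    alt_codon = "".join(mutated[ci * 3 : ci * 3 + 3])
    from Bio.Seq import Seq

    return {
        "gene_id": gene.gene_id,
        "transcript_id": gene.transcript_id,
        "cds_pos": cds_pos,
        "codon_index": ci + 1,
        "codon_pos": (cds_pos - 1) % 3 + 1,
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "ref_aa": str(Seq(ref_codon).translate()),
        "alt_aa": str(Seq(alt_codon).translate()),
    }


def annotate_truth_effects(truth: TruthTable, genes: list, reference: dict) -> TruthTable:
    """Record the true amino-acid consequence of every planted SNV that falls
    inside a CDS."""
    rows = []
    for _, site in truth.planted_sites.iterrows():
        pos0 = int(site["pos"]) - 1
        for gene in genes:
            if gene.scaffold != site["scaffold"] or not gene.in_cds(pos0):
                continue
            eff = _truth_cds_effect(gene, reference, pos0, site["ref"], site["alt"])
            if eff is not None:
                eff.update(scaffold=site["scaffold"], pos=int(site["pos"]))
                rows.append(eff)
    truth.planted_effects = pd.DataFrame(rows)
    return truth


@dataclass
class SimulatedDataset:
    """In-memory objects plus on-disk paths for one simulated study."""

    config: SimConfig
    reference: dict
    genes: list
    matrix: GenotypeMatrix
    truth: TruthTable
    counts: pd.DataFrame
    lengths: pd.Series
    paths: dict


def simulate_dataset(config: SimConfig, outdir) -> SimulatedDataset:
    """Generate and write a complete dataset: FASTA (+ .fai), VCF, popmap,
    GFF3, expression count/length TSVs and the truth-table JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    genes = simulate_gene_models(config, reference)

    paths = {
        "fasta": outdir / "reference.fa",
        "fai": outdir / "reference.fa.fai",
        "vcf": outdir / "variants.vcf",
        "popmap": outdir / "popmap.tsv",
        "gff3": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(reference, paths["fasta"])
    matrix, truth = simulate_genotypes(config, reference)
    write_sim_vcf(matrix, paths["vcf"], config.scaffold_lengths)
    write_popmap(config.populations, paths["popmap"])
    write_gff3(genes, config.scaffold_lengths, paths["gff3"])
    if genes:
        counts, lengths = simulate_expression(genes, 4, config)
    else:  # no genes requested: emit valid empty tables
        counts = pd.DataFrame(columns=list(STAGE_LABELS))
        lengths = pd.Series(dtype=int, name="length")
    counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    lengths.to_csv(paths["lengths"], sep="\t", index_label="gene", header=["length"])
    truth = annotate_truth_effects(truth, genes, reference)
    truth.to_json(paths["truth"])
    return SimulatedDataset(
        config=config,
        reference=reference,
        genes=genes,
        matrix=matrix,
        truth=truth,
        counts=counts,
        lengths=lengths,
        paths={k: str(v) for k, v in paths.items()},
    )
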