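"""Independent brute-force oracles and small builders used across the test
suite.  Everything here is deliberately written with scalar loops and
longhand formulas, separate from the vectorized library code paths."""

from __future__ import annotations

import numpy as np
import pandas as pd

from hdrscan.variants import GenotypeMatrix, SITE_COLUMNS

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984), longhand per site

def wc_components_site(genos_a, genos_b):
    """(a, b, c) for one site from raw dosage lists (-1 = missing), or None
    when the estimator is undefined (an empty population or mean n <= 1)."""
    called_a = [g for g in genos_a if g >= 0]
    called_b = [g for g in genos_b if g >= 0]
    n1, n2 = len(called_a), len(called_b)
    if n1 < 1 or n2 < 1 or (n1 + n2) / 2.0 <= 1.0:
        return None
    p1 = sum(called_a) / (2.0 * n1)
    p2 = sum(called_b) / (2.0 * n2)
    h1 = sum(1 for g in called_a if g == 1) / n1
    h2 = sum(1 for g in called_b if g == 1) / n2

    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_over_sites(matrix: GenotypeMatrix, site_indices=None):
    """Ratio-of-averages FST by direct summation; None if denominator 0."""
    idx_a = matrix.pop_indices("A")
    idx_b = matrix.pop_indices("B")
    rows = range(matrix.n_sites) if site_indices is None else site_indices
    num = den = 0.0
    for i in rows:
        comps = wc_components_site(
            list(matrix.dosage[i, idx_a]), list(matrix.dosage[i, idx_b])
        )
        if comps is None:
            continue
        a, b, c = comps
        num += a
        den += a + b + c
    return None if den <= 0 else num / den


def brute_force_windows(matrix: GenotypeMatrix, scaffold_lengths, window_bp, step_bp,
                        min_scaffold_bp=10_000):
    """Naive per-window FST recomputation: loop windows, loop sites."""
    idx_a = matrix.pop_indices("A")
    idx_b = matrix.pop_indices("B")
    out = {}
    for scaffold, length in scaffold_lengths.items():
        if length <= min_scaffold_bp:
            continue
        start = 0
        while start + window_bp <= length:
            num = den = 0.0
            n_poly = 0
            for i in range(matrix.n_sites):
                row = matrix.sites.iloc[i]
                if row["scaffold"] != scaffold:
                    continue
                pos0 = row["pos"] - 1
                if not start <= pos0 < start + window_bp:
                    continue
                comps = wc_components_site(
                    list(matrix.dosage[i, idx_a]), list(matrix.dosage[i, idx_b])
                )
                if comps is None:
                    continue
                a, b, c = comps
                num += a
                den += a + b + c
                if a + b + c > 0:
                    n_poly += 1
            if n_poly > 0 and den > 0:
                out[(scaffold, start, start + window_bp)] = (n_poly, num / den)
            start += step_bp
    return out


def satisfies_diverged_criterion(genos_a, genos_b, min_called=5):
    """Direct check of the fixation rule on realized genotypes."""
    called_a = [g for g in genos_a if g >= 0]
    called_b = [g for g in genos_b if g >= 0]
    if len(called_a) < min_called or len(called_b) < min_called:
        return False
    for fixed, other in ((called_a, called_b), (called_b, called_a)):
        for allele_dosage in (0, 2):  # REF fixed / ALT fixed
            if all(g == allele_dosage for g in fixed) and all(
                g != allele_dosage for g in other
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# splicing / translation, base by base

def naive_spliced_cds(gene, refdict):
    """Spliced CDS by per-base loops over a dict of scaffold strings."""
    seq = refdict[gene.scaffold]
    segs = sorted(gene.cds_segments, key=lambda s: s.start)
    bases = []
    if gene.strand == "+":
        for seg in segs:
            for p in range(seg.start, seg.end):
                bases.append(seq[p])
    else:
        for seg in reversed(segs):
            for p in range(seg.end - 1, seg.start - 1, -1):
                bases.append(_COMP[seq[p]])
    first_phase = (segs if gene.strand == "+" else segs[::-1])[0].phase
    return "".join(bases[first_phase:])


def naive_translate(cds: str) -> str:
    return "".join(_CODE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def mutate_and_translate(gene, refdict, pos1, alt):
    """Whole-genome mutation oracle: substitute the base, re-splice,
    re-translate; returns (ref_protein, alt_protein, ref_cds, alt_cds)."""
    ref_cds = naive_spliced_cds(gene, refdict)
    seq = refdict[gene.scaffold]
    mutated = dict(refdict)
    mutated[gene.scaffold] = seq[: pos1 - 1] + alt + seq[pos1:]
    alt_cds = naive_spliced_cds(gene, mutated)
    return naive_translate(ref_cds), naive_translate(alt_cds), ref_cds, alt_cds


# ---------------------------------------------------------------------------
# expression

def naive_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for cond in counts.columns:
        total = 0.0
        for g in counts.index:
            total += counts.at[g, cond] / lengths[g]
        for g in counts.index:
            out.at[g, cond] = 1e6 * (counts.at[g, cond] / lengths[g]) / total
    return out


def naive_percentile(tpm: pd.DataFrame, min_tpm=0.0) -> pd.DataFrame:
    out = pd.DataFrame(np.nan, index=tpm.index, columns=tpm.columns)
    for cond in tpm.columns:
        expressed = [g for g in tpm.index if tpm.at[g, cond] > min_tpm]
        for g in expressed:
            greater = sum(1 for h in expressed if tpm.at[h, cond] > tpm.at[g, cond])
            out.at[g, cond] = 100.0 * greater / len(expressed)
    return out


# ---------------------------------------------------------------------------
# builders

def make_matrix(dos_a, dos_b, scaffold="s1", positions=None, dp=None):
    """GenotypeMatrix from per-population dosage arrays (sites x samples)."""
    dos_a = np.asarray(dos_a, dtype=np.int8)
    dos_b = np.asarray(dos_b, dtype=np.int8)
    n_sites = dos_a.shape[0]
    assert dos_b.shape[0] == n_sites
    if positions is None:
        positions = list(range(1, n_sites + 1))
    refalt = [("A", "G")] * n_sites
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_sites,
            "pos": positions,
            "ref": [r for r, _ in refalt],
            "alt": [a for _, a in refalt],
            **{k: [np.nan] * n_sites for k in SITE_COLUMNS[4:]},
        },
        columns=list(SITE_COLUMNS),
    )
    samples = [f"A{i}" for i in range(dos_a.shape[1])] + [
        f"B{i}" for i in range(dos_b.shape[1])
    ]
    pops = {s: s[0] for s in samples}
    return GenotypeMatrix(
        sites=sites,
        dosage=np.hstack([dos_a, dos_b]),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        samples=samples,
        populations=pops,
    )


def random_matrix(rng, max_sites=50, max_per_pop=12, scaffold="s1", span=12_000):
    """Random small matrix with missingness for oracle-equivalence checks."""
    n_sites = int(rng.integers(2, max_sites + 1))
    n_a = int(rng.integers(2, max_per_pop + 1))
    n_b = int(rng.integers(2, max_per_pop + 1))
    dos = rng.choice([0, 1, 2, -1], size=(n_sites, n_a + n_b), p=[0.4, 0.25, 0.25, 0.1])
    positions = sorted(
        int(p) + 1 for p in rng.choice(span, size=n_sites, replace=False)
    )
    return make_matrix(dos[:, :n_a], dos[:, n_a:], scaffold=scaffold, positions=positions)
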