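"""Genotype matrices from multi-sample VCFs, site-level hard filtering, and
per-population allele counts.

The central container is :class:`GenotypeMatrix`: biallelic SNV sites by
samples, genotypes coded as ALT-allele dosage (0, 1, 2; ``-1`` = missing),
with the variant-quality annotations needed for GATK-style hard filtering
carried per site and the per-genotype sequencing depth (FORMAT DP) kept so
that low-coverage calls can be masked individually.

Coordinates are 1-based in VCF records (``pos``) and converted to 0-based
half-open only where intervals are formed (windows, BED output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

#: Annotation keys understood by the hard filter, with the direction in which
#: a value fails: sites fail QD/MQ/rank-sum tests when the value is LOW and
#: fail FS/SOR when the value is HIGH.
FILTER_DIRECTIONS = {
    "QD": "lt",
    "FS": "gt",
    "MQ": "lt",
    "SOR": "gt",
    "MQRankSum": "lt",
    "ReadPosRankSum": "lt",
}

#: Canonical GATK-recommended SNV hard-filter thresholds.  The keys mirror the
#: VCF INFO annotations; all are overridable.
DEFAULT_HARD_FILTERS = {
    "QD": 2.0,
    "FS": 60.0,
    "MQ": 40.0,
    "SOR": 3.0,
    "MQRankSum": -12.5,
    "ReadPosRankSum": -8.0,
}

INFO_FIELDS = tuple(FILTER_DIRECTIONS)

SITE_COLUMNS = ("scaffold", "pos", "ref", "alt") + INFO_FIELDS


@dataclass(frozen=True)
class SiteRecord:
    """A single biallelic SNV site."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"not a biallelic SNV: {self.scaffold}:{self.pos} {self.ref}>{self.alt}"
            )


@dataclass
class GenotypeMatrix:
    """Sites x samples ALT-dosage matrix with population assignments.

    Parameters
    ----------
    sites
        One row per site with columns ``scaffold, pos, ref, alt`` plus the
        hard-filter annotations (NaN when absent from the VCF record).
    dosage
        ``(n_sites, n_samples)`` int8 array of ALT-allele counts per diploid
        genotype; ``-1`` marks a missing call.
    dp
        Per-genotype sequencing depth, same shape as ``dosage``; ``-1`` where
        the VCF carried no DP.  May be ``None``.
    samples
        Ordered sample identifiers (VCF column order).
    populations
        Mapping sample -> population label, labels drawn from ``{"A", "B"}``.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    dp: np.ndarray | None
    samples: list
    populations: dict

    def __post_init__(self):
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")
        bad = {p for p in self.populations.values()} - {"A", "B"}
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_indices(self, pop: str) -> np.ndarray:
        """Column indices of samples belonging to population ``pop``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == pop],
            dtype=int,
        )

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the selected sites."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def site_record(self, i: int) -> SiteRecord:
        row = self.sites.iloc[i]
        info = {k: row[k] for k in INFO_FIELDS if k in row and pd.notna(row[k])}
        return SiteRecord(row["scaffold"], int(row["pos"]), row["ref"], row["alt"], info)


@dataclass
class PopAlleleCounts:
    """Per-site, per-population called-allele summaries.

    ``n_called`` counts diploid samples with a non-missing genotype,
    ``alt_count`` ALT alleles among them, ``het_count`` heterozygous samples.
    The ALT frequency ``p = alt_count / (2 n_called)`` is NaN where a
    population has no called genotype at a site.
    """

    sites: pd.DataFrame
    n_called: dict
    alt_count: dict
    het_count: dict

    pops = ("A", "B")

    def freq(self, pop: str) -> np.ndarray:
        n = self.n_called[pop].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(n > 0, self.alt_count[pop] / (2.0 * n), np.nan)

    def het_freq(self, pop: str) -> np.ndarray:
        n = self.n_called[pop].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(n > 0, self.het_count[pop] / n, np.nan)

    def hom_alt(self, pop: str) -> np.ndarray:
        return (self.alt_count[pop] - self.het_count[pop]) // 2

    def hom_ref(self, pop: str) -> np.ndarray:
        return self.n_called[pop] - self.het_count[pop] - self.hom_alt(pop)


def read_popmap(path) -> dict:
    """Read a two-column TSV mapping sample -> population ("A"/"B")."""
    popmap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            popmap[sample] = pop
    return popmap


def read_vcf(path, popmap) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNV records are kept; indels, multi-allelic and non-SNV
    records are dropped (count logged).  ``popmap`` may be a path to a TSV or
    a ready mapping.  Every VCF sample must appear in the map.
    """
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"VCF samples absent from population map: {absent}")

    rows = []
    dosages = []
    depths = []
    n_dropped = 0
    has_dp = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        if var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            n_dropped += 1
            continue
        row = [var.CHROM, var.POS, var.REF, var.ALT[0]]
        for key in INFO_FIELDS:
            val = var.INFO.get(key)
            row.append(np.nan if val is None else float(val))
        rows.append(row)
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 == unknown
        dosages.append(gt)
        dp = var.format("DP")
        if dp is None:
            depths.append(np.full(len(samples), MISSING, dtype=np.int32))
        else:
            has_dp = True
            dp = dp.reshape(-1).astype(np.int64)
            dp = np.where(dp < 0, MISSING, dp)  # cyvcf2 encodes missing as <0
            depths.append(dp.astype(np.int32))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-SNV/multi-allelic records", n_dropped)

    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    dosage = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    )
    dp_arr = np.vstack(depths) if (depths and has_dp) else None
    pops = {s: popmap[s] for s in samples}
    return GenotypeMatrix(sites, dosage, dp_arr, samples, pops)


def hard_filter_mask(sites: pd.DataFrame, thresholds: dict):
    """Boolean keep-mask for GATK-style hard filtering plus per-criterion
    removal counts.

    A site fails a criterion only when that annotation is present; missing
    annotations never remove a site.
    """
    unknown = set(thresholds) - set(FILTER_DIRECTIONS)
    if unknown:
        raise KeyError(f"unknown hard-filter keys: {sorted(unknown)}")
    keep = np.ones(len(sites), dtype=bool)
    removed = {}
    for key, thr in thresholds.items():
        vals = sites[key].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if FILTER_DIRECTIONS[key] == "lt":
            fails = present & (vals < thr)
        else:
            fails = present & (vals > thr)
        removed[key] = int(fails.sum())
        keep &= ~fails
    return keep, removed


def apply_hard_filters(matrix: GenotypeMatrix, thresholds: dict | None = None) -> GenotypeMatrix:
    """Drop sites failing any present annotation threshold.

    Defaults to the canonical GATK SNV set (:data:`DEFAULT_HARD_FILTERS`).
    """
    if thresholds is None:
        thresholds = DEFAULT_HARD_FILTERS
    keep, removed = hard_filter_mask(matrix.sites, thresholds)
    for key, n in removed.items():
        if n:
            logger.info("hard filter %s removed %d site(s)", key, n)
    return matrix.take_sites(keep)


def mask_low_depth(matrix: GenotypeMatrix, min_dp: int = 4) -> GenotypeMatrix:
    """Set genotypes with DP below ``min_dp`` to missing.

    Genotypes without a DP value are left unmasked (logged).  Sites whose
    called-genotype count drops to zero in either population are removed.
    The default of 4 keeps calls with DP > 3 and excludes the rest as
    low-coverage.
    """
    if matrix.dp is None:
        logger.info("mask_low_depth: matrix carries no DP; nothing masked")
        return matrix
    dosage = matrix.dosage.copy()
    no_dp = matrix.dp == MISSING
    n_no_dp = int(no_dp.sum())
    if n_no_dp:
        logger.info("mask_low_depth: %d genotype(s) without DP left unmasked", n_no_dp)
    low = (~no_dp) & (matrix.dp < min_dp)
    dosage[low] = MISSING
    out = replace(matrix, dosage=dosage)

    idx_a, idx_b = out.pop_indices("A"), out.pop_indices("B")
    called_a = (dosage[:, idx_a] != MISSING).sum(axis=1)
    called_b = (dosage[:, idx_b] != MISSING).sum(axis=1)
    keep = (called_a > 0) & (called_b > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "mask_low_depth: dropped %d site(s) with zero called genotypes in a population",
            n_drop,
        )
    return out.take_sites(keep)


def allele_counts(matrix: GenotypeMatrix) -> PopAlleleCounts:
    """Per-population called/ALT/het counts over called genotypes only."""
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    n_called, alt_count, het_count = {}, {}, {}
    for pop in ("A", "B"):
        idx = matrix.pop_indices(pop)
        sub = matrix.dosage[:, idx]
        called = sub != MISSING
        n_called[pop] = called.sum(axis=1)
        alt_count[pop] = np.where(called, sub, 0).sum(axis=1)
        het_count[pop] = (sub == 1).sum(axis=1)
    return PopAlleleCounts(matrix.sites, n_called, alt_count, het_count)
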