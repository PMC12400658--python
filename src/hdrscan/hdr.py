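"""Diverged-SNV detection and merging of selected FST windows into Highly
Diverged Regions (HDRs).

A *diverged SNV* is a site where one population is fixed for an allele
(frequency 1.0 over called alleles) while the other population carries no
homozygote for that allele — heterozygotes are allowed.  Top-quantile FST
windows containing at least one diverged SNV are merged (overlapping or
book-ended intervals, transitively) into HDRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .fstscan import FstWindow, ScanResult
from .variants import PopAlleleCounts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivergedSNV:
    """A site satisfying the fixation criterion.

    ``fixed_pop`` is the population in which ``fixed_allele`` ("REF"/"ALT")
    reaches frequency 1.0; ``other_pop_het_count`` counts heterozygous
    carriers in the non-fixed population.
    """

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str
    fixed_pop: str
    fixed_allele: str
    other_pop_het_count: int

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def base(self) -> str:
        return self.ref if self.fixed_allele == "REF" else self.alt


@dataclass
class HDR:
    """A merged run of selected windows with its diverged SNVs."""

    scaffold: str
    start: int  # 0-based half-open
    end: int
    member_windows: list
    diverged_snvs: list

    @property
    def max_fst(self) -> float:
        return max(w.fst for w in self.member_windows)

    @property
    def key(self):
        return (self.scaffold, self.start, self.end)


def find_diverged_snvs(counts: PopAlleleCounts, min_called: int = 5) -> list:
    """Scan allele counts for diverged SNVs.

    Fixation is evaluated over called alleles only; sites where either
    population has fewer than ``min_called`` called samples are ineligible
    (logged), so near-empty genotype columns cannot produce fixation calls.
    For a doubly qualifying fixed difference (REF fixed in one population,
    ALT in the other) one record is emitted, for the ALT-fixed population.
    """
    nA, nB = counts.n_called["A"], counts.n_called["B"]
    altA, altB = counts.alt_count["A"], counts.alt_count["B"]
    hetA, hetB = counts.het_count["A"], counts.het_count["B"]
    homaltA, homaltB = counts.hom_alt("A"), counts.hom_alt("B")
    homrefA, homrefB = counts.hom_ref("A"), counts.hom_ref("B")

    eligible = (nA >= min_called) & (nB >= min_called)
    n_inelig = int((~eligible).sum())
    if n_inelig:
        logger.info(
            "find_diverged_snvs: %d site(s) ineligible (fewer than %d called samples)",
            n_inelig,
            min_called,
        )

    # (fixed_pop, allele): fixed in that pop, zero homozygotes in the other.
    tests = [
        ("A", "ALT", (altA == 2 * nA) & (homaltB == 0), hetB),
        ("B", "ALT", (altB == 2 * nB) & (homaltA == 0), hetA),
        ("A", "REF", (altA == 0) & (homrefB == 0), hetB),
        ("B", "REF", (altB == 0) & (homrefA == 0), hetA),
    ]
    out = {}
    sites = counts.sites
    for pop, allele, mask, other_het in tests:
        for i in (eligible & mask).nonzero()[0]:
            if i in out:
                continue
            row = sites.iloc[i]
            out[i] = DivergedSNV(
                scaffold=row["scaffold"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                fixed_pop=pop,
                fixed_allele=allele,
                other_pop_het_count=int(other_het[i]),
            )
    return [out[i] for i in sorted(out)]


def _window_contains(window: FstWindow, snv: DivergedSNV) -> bool:
    return window.scaffold == snv.scaffold and window.start <= snv.pos0 < window.end


def select_hdr_windows(scan: ScanResult, snvs: list) -> list:
    """Top-quantile windows that contain at least one diverged SNV."""
    return [w for w in scan.selected if any(_window_contains(w, s) for s in snvs)]


def merge_windows(windows: list, snvs: list = ()) -> list:
    """Merge overlapping or book-ended windows into HDRs.

    Windows are grouped per scaffold, sorted by start, and merged
    transitively whenever the gap between a window and the growing region is
    <= 0 in half-open coordinates (overlap, or exactly adjacent).  Each HDR
    carries its member windows and the diverged SNVs falling in its span.
    The operation is idempotent and invariant to input order.
    """
    ordered = sorted(windows, key=lambda w: (w.scaffold, w.start, w.end))
    hdrs = []
    for w in ordered:
        if hdrs and hdrs[-1][0] == w.scaffold and w.start <= hdrs[-1][2]:
            scaf, start, end, members = hdrs[-1]
            hdrs[-1] = (scaf, start, max(end, w.end), members + [w])
        else:
            hdrs.append((w.scaffold, w.start, w.end, [w]))
    out = []
    for scaf, start, end, members in hdrs:
        inside = [s for s in snvs if s.scaffold == scaf and start <= s.pos0 < end]
        out.append(
            HDR(scaffold=scaf, start=start, end=end, member_windows=members, diverged_snvs=inside)
        )
    return out


def hdrs_to_frame(hdrs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.scaffold, h.start, h.end, len(h.member_windows), len(h.diverged_snvs), h.max_fst)
            for h in hdrs
        ],
        columns=["scaffold", "start", "end", "n_windows", "n_diverged_snvs", "max_fst"],
    )


def write_hdrs(hdrs: list, bed_path, tsv_path) -> None:
    """Write HDRs as BED (0-based half-open) and a TSV report.

    Output is sorted by scaffold then start; empty inputs produce valid empty
    files.
    """
    ordered = sorted(hdrs, key=lambda h: (h.scaffold, h.start))
    with open(bed_path, "w") as bed:
        for h in ordered:
            bed.write(f"{h.scaffold}\t{h.start}\t{h.end}\n")
    frame = hdrs_to_frame(ordered)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
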