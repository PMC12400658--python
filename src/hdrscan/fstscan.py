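"""Weir & Cockerham (1984) FST: per-site variance components, sliding-window
ratio-of-averages estimates, genome-wide FST, and top-quantile window selection.

For two populations (r = 2) with, at one site, sample sizes ``n_i`` (called
diploids), ALT frequencies ``p_i`` and heterozygote proportions ``h_i``, the
estimator decomposes allelic variance into

* ``a`` — among populations,
* ``b`` — among individuals within populations,
* ``c`` — within individuals (heterozygosity),

and FST over a set of sites is the ratio of averages
``sum(a) / sum(a + b + c)``, not the average of per-site ratios.  A fixed
difference with no heterozygotes gives ``b = c = 0`` and per-site FST exactly
1; sites monomorphic across both populations contribute (0, 0, 0).

Negative per-window values are reported as computed; the top-quantile
selection only looks at the upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix, PopAlleleCounts, allele_counts


class SiteComponents(NamedTuple):
    a: float
    b: float
    c: float


@dataclass(frozen=True)
class FstWindow:
    """A sliding-window interval with its ratio-of-averages FST.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``n_sites``
    counts polymorphic member sites (sites with a + b + c > 0).
    """

    scaffold: str
    start: int
    end: int
    n_sites: int
    fst: float

    @property
    def key(self):
        return (self.scaffold, self.start, self.end)


@dataclass
class ScanResult:
    """All windows, the FST value at the top-quantile cut, and the selection."""

    windows: list
    threshold: float
    selected: list


def _components_from_summaries(n1, n2, p1, p2, h1, h2):
    """Vectorized WC84 (a, b, c) for r = 2 populations.

    Inputs are per-site arrays of called sample sizes, ALT frequencies and
    heterozygote proportions.  Sites where either population has no called
    sample, or where the mean sample size is <= 1 (the estimator is undefined),
    yield NaN components and must be excluded by the caller.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    nbar = (n1 + n2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1.0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def components_all(counts: PopAlleleCounts):
    """Per-site (a, b, c) arrays for every site in ``counts``.

    Sites unusable for the estimator (a population with zero called samples,
    or mean sample size <= 1) come back NaN.
    """
    return _components_from_summaries(
        counts.n_called["A"],
        counts.n_called["B"],
        counts.freq("A"),
        counts.freq("B"),
        counts.het_freq("A"),
        counts.het_freq("B"),
    )


def site_components(counts: PopAlleleCounts, i: int = 0) -> SiteComponents:
    """WC84 components for one site of ``counts``.

    Raises if the site is unusable (a population without called samples).
    """
    a, b, c = components_all(counts)
    if np.isnan(a[i]):
        raise ValueError(f"site {i}: WC estimator undefined (insufficient called samples)")
    return SiteComponents(float(a[i]), float(b[i]), float(c[i]))


def hudson_components(counts: PopAlleleCounts):
    """Per-site Hudson-estimator numerator and denominator (Bhatia et al.
    2013 form), for sensitivity checks against the default estimator:

    N = (p1-p2)^2 - p1(1-p1)/(2n1-1) - p2(1-p2)/(2n2-1);  D = p1(1-p2) + p2(1-p1)

    aggregated, like the default, as a ratio of averages.  Returned as
    (num, den) arrays with NaN where undefined (a population with < 1
    called sample or a single called allele).
    """
    n1 = counts.n_called["A"].astype(float)
    n2 = counts.n_called["B"].astype(float)
    p1, p2 = counts.freq("A"), counts.freq("B")
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (2 * n1 - 1)
            - p2 * (1 - p2) / (2 * n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 1) | (n2 < 1)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


def _usable_components(matrix: GenotypeMatrix, estimator: str = "wc"):
    counts = allele_counts(matrix)
    if estimator == "wc":
        a, b, c = components_all(counts)
    elif estimator == "hudson":
        a, den = hudson_components(counts)
        b = den - a
        c = np.zeros_like(a)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    usable = ~np.isnan(a)
    return counts, a, b, c, usable


def genome_wide_fst(matrix: GenotypeMatrix, estimator: str = "wc") -> float:
    """Ratio-of-averages FST over all retained sites, all scaffolds.

    No scaffold-length filter applies here; the estimate is the single ratio
    ``sum(a) / sum(a + b + c)`` across the genome.  ``estimator="hudson"``
    switches to the Hudson numerator/denominator for sensitivity checks.
    """
    _, a, b, c, usable = _usable_components(matrix, estimator)
    denom = float(np.nansum((a + b + c)[usable]))
    if denom <= 0:
        raise ValueError("no polymorphic sites: genome-wide FST undefined")
    return float(np.nansum(a[usable]) / denom)


def windowed_fst(
    matrix: GenotypeMatrix,
    scaffold_lengths: dict,
    window_bp: int = 10_000,
    step_bp: int = 1_000,
    min_scaffold_bp: int = 10_000,
    estimator: str = "wc",
) -> list:
    """Sliding-window FST along every scaffold strictly longer than
    ``min_scaffold_bp``.

    Windows start at 0 and advance by ``step_bp``; only full windows
    (``start + window_bp <= scaffold length``) are formed and windows never
    span scaffolds.  A site belongs to the window whose half-open interval
    ``[start, end)`` contains its 0-based position.  Windows without
    polymorphic sites (denominator zero) are omitted.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    _, a, b, c, usable = _usable_components(matrix, estimator)
    abc = a + b + c

    sites = matrix.sites
    windows = []
    for scaffold, length in scaffold_lengths.items():
        if length <= min_scaffold_bp:
            continue
        on_scaf = (sites["scaffold"] == scaffold).to_numpy() & usable
        pos0 = sites.loc[on_scaf, "pos"].to_numpy() - 1
        a_s, abc_s = a[on_scaf], abc[on_scaf]
        order = np.argsort(pos0, kind="stable")
        pos0, a_s, abc_s = pos0[order], a_s[order], abc_s[order]
        ca = np.concatenate([[0.0], np.cumsum(a_s)])
        cabc = np.concatenate([[0.0], np.cumsum(abc_s)])
        cpoly = np.concatenate([[0], np.cumsum(abc_s > 0)])

        starts = np.arange(0, length - window_bp + 1, step_bp)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + window_bp, side="left")
        for s, i, j in zip(starts, lo, hi):
            denom = cabc[j] - cabc[i]
            n_poly = int(cpoly[j] - cpoly[i])
            if n_poly == 0 or denom <= 0:
                continue
            windows.append(
                FstWindow(
                    scaffold=scaffold,
                    start=int(s),
                    end=int(s + window_bp),
                    n_sites=n_poly,
                    fst=float((ca[j] - ca[i]) / denom),
                )
            )
    return windows


def top_quantile(windows: list, q: float = 0.001) -> ScanResult:
    """Select the top-``q`` fraction of windows by FST (nearest rank,
    ties at the threshold all included).

    ``k = ceil(q * N)`` windows define the cut; the threshold is the k-th
    highest FST and every window with FST >= threshold is selected.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if not windows:
        raise ValueError("no windows to select from")
    k = math.ceil(q * len(windows))
    fst_desc = sorted((w.fst for w in windows), reverse=True)
    threshold = fst_desc[k - 1]
    selected = sorted(
        (w for w in windows if w.fst >= threshold),
        key=lambda w: (-w.fst, w.scaffold, w.start),
    )
    return ScanResult(windows=list(windows), threshold=threshold, selected=selected)


def windows_to_frame(windows: list) -> pd.DataFrame:
    """Tabular view of windows for TSV output."""
    return pd.DataFrame(
        [(w.scaffold, w.start, w.end, w.n_sites, w.fst) for w in windows],
        columns=["scaffold", "start", "end", "n_sites", "fst"],
    )
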