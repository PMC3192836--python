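"""Derived-SNP sliding-window scan for post-Neanderthal positive selection.

A SNP is human-derived when at least 4 of 6 modern human genomes carry the
derived allele and every observed Neanderthal allele is ancestral.  The
150 kb region upstream of each candidate miRNA precursor is scanned with
50 kb windows at 10 kb steps; each window's derived fraction is compared
against the genome totals by a one-sided Fisher's exact test, Bonferroni-
corrected across all windows in the scan.  Global significance comes from
a feature-anchored permutation null: the same scan on random precursor
subsets, counting how often the random statistic reaches the observed one.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

import numpy as np

from ._stats import fisher_2x2
from .datatypes import ScanSummary, SnpRecord, WindowResult

WINDOW_SIZE = 50_000
STEP = 10_000
UPSTREAM = 150_000
BONFERRONI_ALPHA = 0.05


def classify_derived(record: SnpRecord) -> bool:
    """Human-derived: >= 4 of 6 modern genomes derived AND all observed
    Neanderthal alleles ancestral."""
    return record.derived_count_of_modern >= 4 and record.neanderthal_all_ancestral


def make_windows(region_start0: int, region_end0: int, win: int = WINDOW_SIZE,
                 step: int = STEP) -> list:
    """Half-open sliding windows [s, s+win) for s = start, start+step, ...
    while s+win <= end.  Empty for regions shorter than one window."""
    if region_end0 - region_start0 < win:
        return []
    out = []
    s = region_start0
    while s + win <= region_end0:
        out.append((s, s + win))
        s += step
    return out


def window_fisher(
    n_derived_w: int,
    n_other_w: int,
    n_derived_genome: int,
    n_other_genome: int,
    exclude_window_from_totals: bool = False,
    alternative: str = "greater",
) -> float:
    """One-sided Fisher's exact p for derived-SNP excess in a window
    against the genome totals.  By default the totals include the window's
    own SNPs (window vs genome average); a flag subtracts them.  A window
    with no SNPs has p = 1 by convention."""
    if n_derived_w + n_other_w == 0:
        return 1.0
    dg, og = n_derived_genome, n_other_genome
    if exclude_window_from_totals:
        dg -= n_derived_w
        og -= n_other_w
        if dg < 0 or og < 0:
            raise ValueError("window counts exceed genome totals")
    return fisher_2x2(n_derived_w, n_other_w, dg, og, alternative=alternative)


class _SnpIndex:
    """Sorted position index with per-SNP derived classification."""

    def __init__(self, snps):
        recs = sorted(snps, key=lambda r: (r.chrom, r.pos0))
        self.by_chrom = {}
        for r in recs:
            self.by_chrom.setdefault(r.chrom, ([], []))
            self.by_chrom[r.chrom][0].append(r.pos0)
            self.by_chrom[r.chrom][1].append(classify_derived(r))
        self.n_derived = sum(classify_derived(r) for r in recs)
        self.n_other = len(recs) - self.n_derived

    def count(self, chrom, start0, end0):
        if chrom not in self.by_chrom:
            return 0, 0
        pos, der = self.by_chrom[chrom]
        lo = bisect_left(pos, start0)
        hi = bisect_right(pos, end0 - 1)
        nd = sum(der[lo:hi])
        return nd, (hi - lo) - nd


def upstream_region(precursor, upstream: int = UPSTREAM, contig_start: int = 0,
                    contig_end: int = None) -> tuple:
    """Strand-aware upstream interval: ``upstream`` bp 5' of the precursor
    start, truncated at contig edges (truncation flagged by the caller
    comparing lengths)."""
    if precursor.strand == "+":
        start = max(contig_start, precursor.precursor_start0 - upstream)
        end = precursor.precursor_start0
    else:
        pre_end = precursor.precursor_start0 + len(precursor.precursor_seq)
        start = pre_end
        end = pre_end + upstream
        if contig_end is not None:
            end = min(end, contig_end)
    return precursor.chrom, start, end


def scan_mirna_set(
    precursors,
    snps,
    genome_totals=None,
    win: int = WINDOW_SIZE,
    step: int = STEP,
    upstream: int = UPSTREAM,
    alpha: float = BONFERRONI_ALPHA,
    contig_end: int = None,
    exclude_window_from_totals: bool = False,
) -> list:
    """Scan the upstream region of each precursor in a candidate set.

    The Bonferroni family is all windows tested across the scanned set.
    ``genome_totals`` defaults to the totals of the supplied SNP track.
    Returns one :class:`ScanSummary` per precursor, each carrying its
    windows and the number of Bonferroni-significant ones.
    """
    index = _SnpIndex(snps)
    if genome_totals is None:
        genome_totals = (index.n_derived, index.n_other)
    dg, og = genome_totals
    per_mirna = []
    all_windows = []
    for pre in precursors:
        chrom, start, end = upstream_region(pre, upstream, contig_end=contig_end)
        windows = []
        for ws, we in make_windows(start, end, win, step):
            nd, no = index.count(chrom, ws, we)
            p = window_fisher(nd, no, dg, og,
                              exclude_window_from_totals=exclude_window_from_totals)
            wr = WindowResult(ws, we, nd, no, p)
            windows.append(wr)
            all_windows.append(wr)
        per_mirna.append(ScanSummary(pre.mirna_id, windows))
    m = len(all_windows)
    for summary in per_mirna:
        n_sig = 0
        for w in summary.windows:
            w.bonferroni_significant = m > 0 and w.fisher_p * m < alpha
            n_sig += w.bonferroni_significant
        summary.n_significant_windows = n_sig
    return per_mirna


def scan_statistic(summaries) -> int:
    """The scan statistic for a candidate set: total number of
    Bonferroni-significant windows across the set."""
    return sum(s.n_significant_windows for s in summaries)


def empirical_p(exceedances: int, n_perm: int) -> float:
    """Permutation p as exceedances / n_perm (so 44 of 1000 gives 0.044)."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not 0 <= exceedances <= n_perm:
        raise ValueError("exceedances must be in [0, n_perm]")
    return exceedances / n_perm


def permutation_null(
    pool,
    k: int,
    statistic,
    observed: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """Feature-anchored permutation null.

    Draws ``n_perm`` random ``k``-subsets of ``pool`` without replacement,
    applies ``statistic`` to each, and counts subsets whose statistic is
    >= the observed value.  Returns ``(exceedances, empirical_p)``.
    """
    pool = list(pool)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(len(pool), size=k, replace=False)
        if statistic([pool[i] for i in idx]) >= observed:
            exceed += 1
    return exceed, empirical_p(exceed, n_perm)
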