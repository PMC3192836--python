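"""Differential miRNA expression between species.

Sequencing counts are compared by Fisher's exact test on quantile-
normalized libraries (a miRNA's normalized count against the remainder of
the library), with significance, fold-change and detection criteria
required in both technical replicates with a consistent direction.  Array
intensities are compared by a two-sample t-test after cross-species probe
masking.  The macaque outgroup assigns human-chimpanzee differences to an
evolutionary lineage, and sample relationships are summarised by UPGMA
clustering on correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import binomial_tail_p, fisher_2x2, round_percent
from .datatypes import DECall, LineageCall
from .quantify import DETECTION_THRESHOLD, is_detected

ALPHA = 0.01
FC_MIN = 2.0
#: pseudocount added to both species' normalized counts for fold changes
FC_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# normalization

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the same value multiset (the per-rank mean).

    Ties receive the mean of the reference values over their tied ranks.
    A single column is returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: fewer than 2 columns, returning input unchanged")
        return matrix.copy()
    arr = matrix.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tpm_normalize(counts, total_mapped: float):
    """Counts to transcripts-per-million given the sample's mapped total."""
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be > 0, got {total_mapped}")
    return counts * 1e6 / total_mapped


# ---------------------------------------------------------------------------
# sequencing-based DE

def fisher_count_test(c1: int, N1: int, c2: int, N2: int) -> float:
    """Two-sided Fisher's exact test of one miRNA's count against the
    remainder of each library: table [[c1, N1-c1], [c2, N2-c2]]."""
    if not (0 <= c1 <= N1 and 0 <= c2 <= N2):
        raise ValueError(f"counts exceed totals: ({c1},{N1},{c2},{N2})")
    return fisher_2x2(c1, N1 - c1, c2, N2 - c2)


def call_de_seq(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    species_pair: tuple,
    alpha: float = ALPHA,
    fc_min: float = FC_MIN,
    min_reads: int = DETECTION_THRESHOLD,
) -> list:
    """Sequencing-based DE calls between two species.

    ``counts`` is miRNA x sample; ``samples`` carries ``species`` and
    ``replicate`` per sample id.  With two replicates per species the
    criteria (Fisher p < alpha, fold-change > fc_min, >= min_reads in at
    least one species) must hold in both replicate pairs with the same
    direction.  With a single replicate per species the test falls back to
    single-replicate mode and flags ``replicate_consistent=None``.
    """
    sp1, sp2 = species_pair
    reps1 = samples.index[samples["species"] == sp1]
    reps2 = samples.index[samples["species"] == sp2]
    if len(reps1) == 0 or len(reps2) == 0:
        raise ValueError(f"no samples for species pair {species_pair}")
    by_rep1 = {int(samples.loc[s, "replicate"]): s for s in reps1}
    by_rep2 = {int(samples.loc[s, "replicate"]): s for s in reps2}
    shared_reps = sorted(set(by_rep1) & set(by_rep2))
    single_mode = len(shared_reps) < 2
    per_rep = []
    for r in shared_reps:
        s1, s2 = by_rep1[r], by_rep2[r]
        pair = counts[[s1, s2]].astype(float)
        norm = quantile_normalize(pair)
        c = norm.round().astype(int).clip(lower=0)
        N1 = int(c[s1].sum())
        N2 = int(c[s2].sum())
        res = {}
        for mid in counts.index:
            c1, c2 = int(c.loc[mid, s1]), int(c.loc[mid, s2])
            p = fisher_count_test(c1, N1, c2, N2)
            fc = (c1 + FC_PSEUDOCOUNT) / (c2 + FC_PSEUDOCOUNT)
            detected = is_detected(int(counts.loc[mid, s1]), min_reads) or is_detected(
                int(counts.loc[mid, s2]), min_reads
            )
            res[mid] = (p, fc, detected)
        per_rep.append(res)
    calls = []
    for mid in counts.index:
        ps = [r[mid][0] for r in per_rep]
        fcs = [r[mid][1] for r in per_rep]
        dets = [r[mid][2] for r in per_rep]
        dirs = ["up-in-1" if fc > 1 else "up-in-2" for fc in fcs]
        crit = [
            p < alpha and max(fc, 1.0 / fc) > fc_min and det
            for p, fc, det in zip(ps, fcs, dets)
        ]
        same_dir = len(set(dirs)) == 1
        passed = all(crit) and same_dir and len(crit) > 0
        fc_geo = float(np.exp(np.mean(np.log(fcs))))
        calls.append(
            DECall(
                mirna_id=mid,
                p_value=float(max(ps)),
                fold_change=fc_geo,
                direction="up-in-1" if fc_geo > 1 else "up-in-2",
                passed=passed,
                replicate_consistent=None
                if single_mode
                else (same_dir and (all(crit) or not any(crit))),
                detected=any(dets),
            )
        )
    return calls


def edger_filter(table: pd.DataFrame, p_max: float = 0.001, fdr_max: float = 0.01):
    """Hook for an externally computed negative-binomial exact test.

    ``table`` must carry ``p`` and ``fdr`` columns indexed by miRNA id;
    returns the ids passing the published filter.  The NB test itself is
    an external package and is deliberately not reimplemented here.
    """
    missing = {"p", "fdr"} - set(table.columns)
    if missing:
        raise ValueError(f"edgeR table missing column(s): {sorted(missing)}")
    mask = (table["p"] < p_max) & (table["fdr"] < fdr_max)
    return list(table.index[mask])


# ---------------------------------------------------------------------------
# array-based DE

def call_de_array(
    intensities: pd.DataFrame,
    species_of: dict,
    species_pair: tuple,
    masked_ids=(),
    alpha: float = ALPHA,
    fc_min: float = FC_MIN,
) -> list:
    """Array-based DE calls on quantile-normalized log2 intensities.

    Masked miRNA (cross-species mature-sequence differences) are excluded
    before testing; miRNA with fewer than 2 individuals per species are
    skipped with a flag.
    """
    sp1, sp2 = species_pair
    cols1 = [c for c in intensities.columns if species_of[c] == sp1]
    cols2 = [c for c in intensities.columns if species_of[c] == sp2]
    calls = []
    masked = set(masked_ids)
    for mid in intensities.index:
        if mid in masked:
            continue
        x = intensities.loc[mid, cols1].to_numpy(dtype=float)
        y = intensities.loc[mid, cols2].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            calls.append(DECall(mid, float("nan"), 1.0, "up-in-1", False, detected=False))
            continue
        t, p = stats.ttest_ind(x, y)
        fc = float(2.0 ** (x.mean() - y.mean()))  # intensities are log2
        passed = bool(p < alpha and max(fc, 1.0 / fc) > fc_min)
        calls.append(
            DECall(mid, float(p), fc, "up-in-1" if fc > 1 else "up-in-2", passed)
        )
    return calls


# ---------------------------------------------------------------------------
# cross-platform / cross-region agreement and lineage assignment

def direction_consistency(calls_a, calls_b) -> tuple:
    """Agreement of divergence direction between two call sets.

    For miRNA passing in ``calls_a`` and present in ``calls_b``, counts
    those with the same direction in ``calls_b``.  Returns
    ``(n_shared, n_consistent, percent, binomial_p)`` where the percent is
    rounded to the nearest integer and the binomial p is the one-sided
    exact tail P(X >= n_consistent | n_shared, 1/2).
    """
    dir_b = {c.mirna_id: c.direction for c in calls_b}
    shared = [c for c in calls_a if c.passed and c.mirna_id in dir_b]
    if not shared:
        raise ValueError("no shared miRNA between the two call sets")
    n_shared = len(shared)
    n_consistent = sum(1 for c in shared if dir_b[c.mirna_id] == c.direction)
    return (
        n_shared,
        n_consistent,
        round_percent(n_consistent, n_shared),
        binomial_tail_p(n_consistent, n_shared),
    )


def assign_lineage(
    mirna_id: str,
    expr_h: float,
    expr_c: Optional[float] = None,
    expr_m: Optional[float] = None,
) -> LineageCall:
    """Assign a human-chimpanzee expression difference to one lineage
    using the macaque level as the inferred ancestral state.

    Human lineage: the human level is further from the macaque level than
    the chimpanzee level is, and the chimpanzee level lies on the macaque
    side of the human level (so the change happened on the human branch).
    Chimpanzee lineage by the mirrored rule; anything else is unassigned.
    """
    if expr_m is None:
        return LineageCall(mirna_id, "unassigned", outgroup_missing=True)
    dh = abs(expr_h - expr_m)
    dc = abs(expr_c - expr_m)
    if dh > dc and (expr_c - expr_h) * (expr_m - expr_h) > 0:
        return LineageCall(mirna_id, "human")
    if dc > dh and (expr_h - expr_c) * (expr_m - expr_c) > 0:
        return LineageCall(mirna_id, "chimpanzee")
    return LineageCall(mirna_id, "unassigned")


# ---------------------------------------------------------------------------
# clustering

@dataclass
class Dendrogram:
    """Binary UPGMA tree node: leaves carry a label, internal nodes a
    height (half the merge distance) and two children."""

    height: float = 0.0
    label: Optional[str] = None
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.label]
        return [x for ch in self.children for x in ch.leaves()]

    def newick(self) -> str:
        def _fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf():
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(_fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{bl:.6g}"

        if self.is_leaf():
            return f"{self.label};"
        inner = ",".join(_fmt(ch, self.height) for ch in self.children)
        return f"({inner});"


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns."""
    arr = matrix.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"constant column: sample {matrix.columns[j]!r}")
    d = 1.0 - np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def upgma_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram of samples on 1 - Pearson correlation distance."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    return upgma_from_distances(correlation_distance(matrix))


def upgma_from_distances(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration on a symmetric distance matrix.

    Deterministic: among tied minimal distances the pair containing the
    smallest original sample index (then the smallest partner) merges
    first.  Node heights are half the merge distance, so the tree is
    ultrametric; cluster-to-cluster distances are unweighted averages
    over the original leaves.
    """
    dist = distances.to_numpy(dtype=float)
    labels = list(distances.columns)
    clusters = {
        i: {"node": Dendrogram(label=labels[i]), "members": [i], "min_idx": i}
        for i in range(len(labels))
    }
    d = {(i, j): dist[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    while len(clusters) > 1:
        best = min(
            d,
            key=lambda k: (
                d[k],
                min(clusters[k[0]]["min_idx"], clusters[k[1]]["min_idx"]),
                max(clusters[k[0]]["min_idx"], clusters[k[1]]["min_idx"]),
            ),
        )
        i, j = best
        h = d[best] / 2.0
        ni, nj = len(clusters[i]["members"]), len(clusters[j]["members"])
        new = max(clusters) + 1
        node = Dendrogram(height=h, children=[clusters[i]["node"], clusters[j]["node"]])
        merged = {
            "node": node,
            "members": clusters[i]["members"] + clusters[j]["members"],
            "min_idx": min(clusters[i]["min_idx"], clusters[j]["min_idx"]),
        }
        # unweighted average over original leaves
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[tuple(sorted((new, k)))] = (ni * dik + nj * djk) / (ni + nj)
        for key in [k for k in d if i in k or j in k]:
            del d[key]
        del clusters[i], clusters[j]
        clusters[new] = merged
    return next(iter(clusters.values()))["node"]


# ---------------------------------------------------------------------------
# Q-PCR

def qpcr_relative_expression(ct_mirna: float, ct_reference: float) -> float:
    """log2 relative level from threshold cycles, normalized to the
    endogenous control: log2(2^-(Ct_miRNA - Ct_ref)) = -(Ct_miRNA - Ct_ref)."""
    return -(ct_mirna - ct_reference)
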