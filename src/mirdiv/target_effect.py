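"""Effect of miRNA expression divergence on mRNA and protein divergence.

The central quantities: a rank-based shift test comparing the divergence
of targets of human-high versus chimp-high miRNA; an association count
classifying each significantly diverged gene as negatively or positively
associated with the miRNA divergence that targets it; the headline
"percent explained" statistic, 100*(negative - positive)/total; a
label-permutation FDR for the divergence significance cutoff; and the
inhibition-ratio / Fisher-enrichment statistics used for transfection and
lineage comparisons.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_2x2, round_percent
from .datatypes import AssociationSummary

#: genes with smaller absolute mRNA divergence are excluded from the shift test
MIN_ABS_DIVERGENCE = 0.5
#: genes with |standardized effect size| <= this are excluded (protein level)
MIN_ABS_EFFECT_SIZE = 1.0


def divergence_shift_test(
    divergences: pd.Series,
    targets_of_human_high,
    targets_of_chimp_high,
    min_abs: float = MIN_ABS_DIVERGENCE,
) -> tuple:
    """Rank-based comparison of divergence between the two target groups.

    Genes targeted by both groups (inconsistent expected effects) are
    excluded, as are genes with |divergence| < ``min_abs``.  The
    comparison is the unpaired two-sample rank-sum (Mann-Whitney) test,
    two-sided, exact for small groups.  Under the regulatory model the
    targets of human-high miRNA sit lower (more negative human/chimp
    divergence).  Returns ``(p, median_human_high, median_chimp_high)``.
    """
    both = set(targets_of_human_high) & set(targets_of_chimp_high)
    gh = [g for g in set(targets_of_human_high) - both if g in divergences.index]
    gc = [g for g in set(targets_of_chimp_high) - both if g in divergences.index]
    x = divergences.loc[gh]
    y = divergences.loc[gc]
    x = x[x.abs() >= min_abs].to_numpy(dtype=float)
    y = y[y.abs() >= min_abs].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("no testable targets after filtering")
    method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue), float(np.median(x)), float(np.median(y))


def protein_effect_size(values_h, values_c) -> float:
    """Standardized mean difference (pooled-SD Cohen's d, no small-sample
    correction): (mean_h - mean_c) / pooled SD.  Returns NaN (gene should
    be flagged) when the pooled SD is zero."""
    x = np.asarray(values_h, dtype=float)
    y = np.asarray(values_c, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 replicates per species")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def filter_by_effect_size(effect_sizes: pd.Series, min_abs: float = MIN_ABS_EFFECT_SIZE) -> pd.Series:
    """Keep genes with |standardized effect size| strictly greater than
    ``min_abs`` (protein-level divergence filter); NaN effects drop out."""
    return effect_sizes[effect_sizes.abs() > min_abs]


def count_associations(
    de_calls,
    target_map: dict,
    divergence: pd.Series,
    sig_mask: pd.Series,
) -> AssociationSummary:
    """Classify each significantly diverged gene by its relation to the DE
    miRNA targeting it.

    A gene is negatively associated when at least one miRNA-gene pair has
    opposite directions (miRNA up in the species where the gene is down);
    positively associated when it has pairs and none are opposite.
    Opposite-direction evidence is decisive.  ``divergence`` is signed
    with positive = higher in human; miRNA direction "up-in-1" = up in
    human.
    """
    sig_genes = list(sig_mask.index[sig_mask.astype(bool)])
    n_total = len(sig_genes)
    passed = [c for c in de_calls if c.passed]
    n_neg = n_pos = 0
    for g in sig_genes:
        if g not in divergence.index:
            continue
        d = divergence.loc[g]
        has_pair = False
        has_opposite = False
        for c in passed:
            if g not in target_map.get(c.mirna_id, ()):
                continue
            has_pair = True
            mirna_up_in_human = c.direction == "up-in-1"
            gene_up_in_human = d > 0
            if mirna_up_in_human != gene_up_in_human:
                has_opposite = True
                break
        if has_opposite:
            n_neg += 1
        elif has_pair:
            n_pos += 1
    return summarize_associations(n_neg, n_pos, n_total)


def summarize_associations(n_negative: int, n_positive: int, n_total: int) -> AssociationSummary:
    """Build the association summary with rounded printed-style percents."""
    if n_negative + n_positive > n_total:
        raise ValueError("associated genes exceed the significant total")
    if n_total == 0:
        return AssociationSummary(0, 0, 0)
    return AssociationSummary(
        n_total_significant=n_total,
        n_negative=n_negative,
        n_positive=n_positive,
        percent_negative=round_percent(n_negative, n_total),
        percent_positive=round_percent(n_positive, n_total),
        percent_explained=round_percent(n_negative - n_positive, n_total),
    )


def permutation_fdr(
    expression: pd.DataFrame,
    species_labels,
    alpha: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """FDR of a per-gene two-sample t-test at cutoff ``alpha``, estimated
    by whole-column species-label permutations.

    FDR = mean over permutations of (#significant under permuted labels)
    divided by #significant observed; NaN when nothing is observed
    significant.  Returns ``(n_significant_observed, fdr)``.
    """
    labels = np.asarray(list(species_labels))
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 species, got {list(groups)}")
    arr = expression.to_numpy(dtype=float)
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 samples per species")

    def n_sig(lab):
        a = arr[:, lab == groups[0]]
        b = arr[:, lab == groups[1]]
        p = stats.ttest_ind(a, b, axis=1).pvalue
        return int((p < alpha).sum())

    observed = n_sig(labels)
    if observed == 0:
        return 0, float("nan")
    rng = np.random.default_rng(seed)
    perm_counts = [n_sig(rng.permutation(labels)) for _ in range(n_perm)]
    return observed, float(np.mean(perm_counts) / observed)


def inhibition_ratio(group_down: int, group_not_down: int) -> float:
    """Down-regulated genes divided by not-down-regulated genes; infinity
    when the denominator is zero (flagged by the caller)."""
    if group_down < 0 or group_not_down < 0:
        raise ValueError("counts must be non-negative")
    if group_not_down == 0:
        return float("inf")
    return group_down / group_not_down


def fisher_enrichment(a_down: int, a_not: int, b_down: int, b_not: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 of
    (group A, group B) x (down, not down)."""
    return fisher_2x2(a_down, a_not, b_down, b_not)
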