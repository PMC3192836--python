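"""Experimentally verified targets from miRNA transfection experiments.

A predicted target is verified when it is inhibited (log-ratio below an
inhibition cutoff) in both cell lines, at the loosest cutoff where the
proportion-based FDR — the fraction of non-targets passing over the
fraction of predicted targets passing — drops below the requested level.
Verified sets from several prediction algorithms are unioned.  The module
also classifies human-specific gene expression using the outgroup and
tests whether verified targets with human-specific expression are
preferentially inhibited on the human lineage.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._stats import fisher_2x2
from .datatypes import VerifiedTargetSet
from .target_effect import inhibition_ratio

#: default FDR level for target verification
DEFAULT_FDR = 0.10
#: inhibition-cutoff scan grid, loosest first (log2 ratio units)
CUTOFF_GRID = tuple(np.round(np.arange(0.0, -2.0001, -0.05), 2))


def per_line_effects(transfection: pd.DataFrame) -> pd.DataFrame:
    """Average the two mock-referenced columns of each cell line.

    Input columns are ``<cell line>:mock1`` / ``:mock2``; output is one
    effect column per cell line.
    """
    lines = sorted({c.split(":")[0] for c in transfection.columns})
    out = {}
    for cl in lines:
        cols = [c for c in transfection.columns if c.split(":")[0] == cl]
        out[cl] = transfection[cols].mean(axis=1)
    return pd.DataFrame(out, index=transfection.index)


def _pass_mask(effects: pd.DataFrame, cutoff: float, require_both: bool = True) -> pd.Series:
    """Genes inhibited at ``cutoff`` in both cell lines (or any one, when
    ``require_both`` is off)."""
    hit = effects <= cutoff
    return hit.all(axis=1) if require_both else hit.any(axis=1)


def transfection_fdr(
    target_effects: pd.DataFrame,
    nontarget_effects: pd.DataFrame,
    cutoff: float,
    denominator: str = "passing",
    require_both: bool = True,
) -> float:
    """Proportion-based FDR at one inhibition cutoff.

    Default reading (``denominator="passing"``): the fraction of
    non-targets passing the cutoff divided by the fraction of predicted
    targets passing it.  The alternative reading
    (``denominator="expressed"``) divides by the fraction of expressed
    genes that are predicted targets.  NaN when the denominator is zero.
    """
    if cutoff > 0:
        raise ValueError(f"inhibition cutoff must be <= 0, got {cutoff}")
    if len(target_effects) == 0:
        raise ValueError("empty target set")
    frac_nt = float(_pass_mask(nontarget_effects, cutoff, require_both).mean()) if len(
        nontarget_effects
    ) else 0.0
    if denominator == "passing":
        frac_t = float(_pass_mask(target_effects, cutoff, require_both).mean())
    elif denominator == "expressed":
        frac_t = len(target_effects) / (len(target_effects) + len(nontarget_effects))
    else:
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    if frac_t == 0:
        return float("nan")
    return frac_nt / frac_t


def verified_union(
    target_maps: dict,
    effects: pd.DataFrame,
    mirna_id: str,
    fdr_cutoff: float = DEFAULT_FDR,
    per_mirna_overrides: dict = None,
    cutoff_grid=CUTOFF_GRID,
    denominator: str = "passing",
) -> VerifiedTargetSet:
    """Union over algorithms of targets verified at FDR < cutoff.

    ``target_maps`` maps algorithm name to {miRNA -> predicted gene set};
    ``effects`` is the per-cell-line effect matrix (genes x cell lines)
    for ``mirna_id`` — its index defines the expressed-gene universe.  For
    each algorithm the scan walks the cutoff grid from loosest to
    strictest and selects the first (loosest) cutoff achieving
    FDR < cutoff; that algorithm contributes its passing predicted
    targets.  ``per_mirna_overrides`` substitutes a different FDR level
    for specific miRNA.
    """
    fdr = (per_mirna_overrides or {}).get(mirna_id, fdr_cutoff)
    expressed = set(effects.index)
    union = set()
    contributing = {}
    if fdr >= 1.0:
        # no verification filter: every predicted target expressed in a
        # cell line qualifies (upper-bound mode)
        for alg in sorted(target_maps):
            predicted = set(target_maps[alg].get(mirna_id, ())) & expressed
            if predicted:
                union |= predicted
                contributing[alg] = 0.0
        return VerifiedTargetSet(mirna_id, union, fdr, contributing, empty_flag=not union)
    for alg in sorted(target_maps):
        predicted = set(target_maps[alg].get(mirna_id, ())) & expressed
        if not predicted:
            continue
        t_eff = effects.loc[sorted(predicted)]
        nt_eff = effects.loc[sorted(expressed - predicted)]
        for cutoff in cutoff_grid:
            val = transfection_fdr(t_eff, nt_eff, cutoff, denominator=denominator)
            if not math.isnan(val) and val < fdr:
                passing = set(t_eff.index[_pass_mask(t_eff, cutoff)])
                if passing:
                    union |= passing
                    contributing[alg] = float(cutoff)
                break
    return VerifiedTargetSet(
        mirna_id=mirna_id,
        genes=union,
        fdr_cutoff=fdr,
        contributing_algorithms=contributing,
        empty_flag=not union,
    )


def classify_human_specific(expr_h: float, expr_c: float, expr_m: float) -> bool:
    """True when the human-macaque expression distance exceeds the
    chimpanzee-macaque distance (human-specific expression)."""
    if expr_m is None or (isinstance(expr_m, float) and math.isnan(expr_m)):
        raise ValueError("missing macaque (outgroup) expression")
    return abs(expr_h - expr_m) > abs(expr_c - expr_m)


def lineage_inhibition_test(
    verified: VerifiedTargetSet,
    divergence_sign: dict,
    mirna_up_in_human: bool,
    human_specific: set,
) -> tuple:
    """Inhibition ratios of human-specific vs remaining verified targets.

    A gene counts as inhibited when its human-chimpanzee divergence
    direction is opposite to the miRNA's (``divergence_sign`` maps gene to
    +1 for higher-in-human / -1 for lower-in-human).  Returns
    ``(ratio_hs, ratio_rest, fisher_p)``; a ratio is NaN when its
    partition is empty.
    """
    hs = [g for g in verified.genes if g in human_specific and g in divergence_sign]
    rest = [g for g in verified.genes if g not in human_specific and g in divergence_sign]
    mirna_sign = 1 if mirna_up_in_human else -1

    def split(genes):
        down = sum(1 for g in genes if divergence_sign[g] == -mirna_sign)
        return down, len(genes) - down

    hs_down, hs_not = split(hs)
    rest_down, rest_not = split(rest)
    ratio_hs = inhibition_ratio(hs_down, hs_not) if hs else float("nan")
    ratio_rest = inhibition_ratio(rest_down, rest_not) if rest else float("nan")
    if not hs or not rest:
        return ratio_hs, ratio_rest, float("nan")
    p = fisher_2x2(hs_down, hs_not, rest_down, rest_not)
    return ratio_hs, ratio_rest, p
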