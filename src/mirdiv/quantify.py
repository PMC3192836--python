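"""5'-anchored miRNA quantification from small-RNA read stacks.

A miRNA's expression is counted from reads whose genomic 5' position falls
within three nucleotides of the annotated mature 5' position (inclusive on
both sides).  Among the retained sequences, the one with the maximal copy
number is the reference; the reported count is the reference's copies plus
the copies of every other retained sequence sharing the reference's 5'
position.  Reads at retained-but-different 5' positions are 5' isoforms
and are not summed — this is what anchors the estimate to a single 5' end.

Novel star-arm detection: on a precursor with one annotated mature arm,
the maximal-copy sequence on the opposite arm is a candidate novel miRNA,
accepted when at least 14 bases separate it from the annotated mature
within the precursor (linear precursor distance between the two intervals).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional

import pandas as pd

from .datatypes import MirnaCount, MirnaLocus, ReadStack

#: window half-width around the mature 5' position ("within three
#: nucleotides", read inclusively: |offset| <= 3)
WINDOW = 3
#: minimal separation (nt between intervals on the precursor) for a novel
#: star candidate
MIN_STAR_SEPARATION = 14
#: detection threshold in sequence reads
DETECTION_THRESHOLD = 10


def _aggregate(records):
    """Collapse duplicate (sequence, chrom, pos0, strand) entries."""
    agg = defaultdict(int)
    for r in records:
        agg[(r.sequence, r.chrom, r.pos0, r.strand)] += r.copies
    return [
        {"sequence": k[0], "chrom": k[1], "pos0": k[2], "strand": k[3], "copies": v}
        for k, v in agg.items()
    ]


def quantify_mirna(stack: ReadStack, locus: MirnaLocus, window: int = WINDOW) -> MirnaCount:
    """Count one miRNA in one sample by the 5'-anchored rule."""
    m5 = locus.mature_5p_genomic()
    retained = []
    n_strand_skipped = 0
    for rec in _aggregate(stack.records):
        if rec["chrom"] != locus.chrom:
            continue
        if abs(rec["pos0"] - m5) > window:
            continue
        if rec["strand"] != locus.strand:
            n_strand_skipped += 1
            continue
        retained.append(rec)
    if not retained:
        return MirnaCount(locus.mirna_id, stack.sample_id, 0, "", n_strand_skipped)
    # maximal copy number; ties broken by lexicographically smallest sequence
    ref = min(retained, key=lambda r: (-r["copies"], r["sequence"]))
    count = sum(r["copies"] for r in retained if r["pos0"] == ref["pos0"])
    return MirnaCount(locus.mirna_id, stack.sample_id, count, ref["sequence"], n_strand_skipped)


def quantify_stacks(stacks, loci_by_species) -> pd.DataFrame:
    """Quantify every locus in every sample.

    ``loci_by_species`` maps species name to its locus list (as produced by
    the synthetic generator); returns a miRNA x sample count matrix.
    """
    columns = {}
    index = None
    for stack in stacks:
        loci = loci_by_species[stack.species]
        ids = [lc.mirna_id for lc in loci]
        if index is None:
            index = ids
        columns[stack.sample_id] = [quantify_mirna(stack, lc).count for lc in loci]
    out = pd.DataFrame(columns, index=index)
    out.index.name = "mirna_id"
    return out


def detect_novel_star(
    locus: MirnaLocus,
    opposite_arm_records,
    min_separation: int = MIN_STAR_SEPARATION,
) -> Optional[tuple]:
    """Novel star-arm candidate from reads on the arm opposite the
    annotated mature.

    ``opposite_arm_records`` is a list of ``(sequence, start0, copies)``
    with ``start0`` in precursor coordinates.  Returns
    ``(sequence, start0, copies)`` for an accepted candidate, else None.
    """
    if not opposite_arm_records:
        return None
    seq, start, copies = min(opposite_arm_records, key=lambda r: (-r[2], r[0]))
    cand_start, cand_end = start, start + len(seq)
    if cand_start >= locus.mature_end0:
        separation = cand_start - locus.mature_end0
    elif cand_end <= locus.mature_start0:
        separation = locus.mature_start0 - cand_end
    else:  # overlap with the annotated mature
        separation = -1
    if separation >= min_separation:
        return (seq, start, copies)
    return None


def is_detected(count: int, threshold: int = DETECTION_THRESHOLD) -> bool:
    """A miRNA is detected when covered by at least ``threshold`` reads."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count >= threshold
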