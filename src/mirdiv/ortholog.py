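"""Cross-species precursor ortholog assignment and mature projection.

The external mappers (whole-genome alignment tools) are not executed here;
this module consumes their hit tables and applies the consensus logic: a
length filter on each hit, grouping of hits into candidate loci by
reciprocal overlap, and a 2-of-3 method-support rule with an ambiguity
veto.  Mature sequences are projected onto the ortholog by global pairwise
alignment of the two precursors.
"""

from __future__ import annotations

from typing import Optional

from Bio import Align

from .datatypes import OrthologCall, OrthologHit

#: strict length-filter bounds relative to the query length
LENGTH_MIN_FRACTION = 0.70
LENGTH_MAX_FRACTION = 1.30
#: two hits describe the same locus when each covers >= this fraction of
#: the other (reciprocal-overlap grouping; locus identity across mapping
#: methods is otherwise undefined)
RECIPROCAL_OVERLAP = 0.5
#: minimal number of distinct supporting methods
MIN_METHODS = 2

# Affine scoring for precursor-precursor alignment.  The projection is
# insensitive to the exact scheme for the closely related sequences this
# module sees (independent aligners agree to well under 0.1% on such
# pairs); the scheme is fixed here so results are reproducible.
MATCH = 1
MISMATCH = -1
GAP_OPEN = -5
GAP_EXTEND = -1


def filter_hit_by_length(query_len: int, hit_len: int) -> bool:
    """Keep hits strictly between 70% and 130% of the query length."""
    if query_len <= 0 or hit_len <= 0:
        raise ValueError(f"lengths must be positive, got ({query_len}, {hit_len})")
    return query_len * LENGTH_MIN_FRACTION < hit_len < query_len * LENGTH_MAX_FRACTION


def _same_locus(a: OrthologHit, b: OrthologHit) -> bool:
    if a.target_chrom != b.target_chrom or a.target_species != b.target_species:
        return False
    ov = min(a.target_end0, b.target_end0) - max(a.target_start0, b.target_start0)
    if ov <= 0:
        return False
    la = a.target_end0 - a.target_start0
    lb = b.target_end0 - b.target_start0
    return ov >= RECIPROCAL_OVERLAP * la and ov >= RECIPROCAL_OVERLAP * lb


def call_ortholog(hits) -> tuple:
    """Consensus ortholog call for one query precursor.

    Groups hits into candidate loci (single linkage on reciprocal
    overlap), then requires a unique locus supported by at least 2 of the
    3 mapping methods.  Returns ``(call_or_None, status)`` with status in
    ``{"called", "no_support", "ambiguous", "no_hits"}``.
    """
    hits = list(hits)
    if not hits:
        return None, "no_hits"
    queries = {h.query_precursor_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from mixed queries: {sorted(queries)}")
    # single-linkage grouping
    parent = list(range(len(hits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if _same_locus(hits[i], hits[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i, h in enumerate(hits):
        groups.setdefault(find(i), []).append(h)
    supported = [
        g for g in groups.values() if len({h.method for h in g}) >= MIN_METHODS
    ]
    if not supported:
        return None, "no_support"
    if len(supported) > 1:
        return None, "ambiguous"
    g = supported[0]
    call = OrthologCall(
        query_precursor_id=hits[0].query_precursor_id,
        target_chrom=g[0].target_chrom,
        target_start0=min(h.target_start0 for h in g),
        target_end0=max(h.target_end0 for h in g),
        supporting_methods=frozenset(h.method for h in g),
    )
    return call, "called"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def extract_mature_ortholog(
    query_precursor_seq: str,
    target_precursor_seq: str,
    mature_interval_on_query: tuple,
) -> tuple:
    """Project a mature interval from the query precursor onto the target.

    Globally aligns the two precursors and takes the target residues
    aligned to the query mature columns, gap columns dropped.  Returns
    ``(mature_ortholog_seq, (target_start0, target_end0))``.
    """
    if not query_precursor_seq or not target_precursor_seq:
        raise ValueError("precursor sequences must be non-empty")
    ms, me = mature_interval_on_query
    if not 0 <= ms < me <= len(query_precursor_seq):
        raise ValueError(f"mature interval [{ms},{me}) outside query precursor")
    aln = _aligner().align(query_precursor_seq, target_precursor_seq)[0]
    pieces = []
    t_lo, t_hi = None, None
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        lo = max(qs, ms)
        hi = min(qe, me)
        if lo < hi:
            a = ts + (lo - qs)
            b = ts + (hi - qs)
            pieces.append(target_precursor_seq[a:b])
            t_lo = a if t_lo is None else min(t_lo, a)
            t_hi = b if t_hi is None else max(t_hi, b)
    if not pieces or not any(pieces):
        raise ValueError("mature unalignable: empty projection on target")
    return "".join(pieces), (t_lo, t_hi)


def mask_for_array(mature_a: str, mature_b: str) -> bool:
    """True when two mature sequences differ anywhere (probes for such
    miRNA cannot be compared across species and are masked)."""
    if not mature_a or not mature_b:
        raise ValueError("mature sequences must be non-empty")
    return mature_a != mature_b


def project_call(call: Optional[OrthologCall], query_seq: str, target_seq: str,
                 mature_interval: tuple) -> Optional[OrthologCall]:
    """Fill in the mature projection and array-mask flag on a call."""
    if call is None:
        return None
    mature_q = query_seq[mature_interval[0] : mature_interval[1]]
    mature_t, _ = extract_mature_ortholog(query_seq, target_seq, mature_interval)
    call.mature_ortholog_seq = mature_t
    call.mask_for_array = mask_for_array(mature_q, mature_t)
    return call
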