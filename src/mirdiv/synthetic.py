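"""Seeded generators for every input the pipeline consumes.

The generators implant known signal — differentially expressed miRNA,
down-shifted target genes, inhibited transfection targets, derived-SNP
excess windows — and return the ground truth alongside the data, so every
downstream stage can be tested for recovery and calibration without any
external data.

Count model: negative binomial via a gamma-Poisson mixture.  Per-miRNA
relative abundances are log-normal; the per-sample expected count is
``depth * p_i``, multiplied by ``de_fold`` in the up-species for implanted
DE miRNA.  Reads are placed at 5' offsets -3..+3 around the annotated
mature 5' position (most at offset 0), plus decoy reads at offsets +/-5 —
beyond the quantification window — at 5% of each miRNA's count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STAGE_OFFSETS, SimConfig
from .datatypes import GroundTruth, MirnaLocus, ReadRecord, ReadStack, SnpRecord
from .errors import ConfigError, DimensionError

#: probability of each 5' offset -3..+3 within the quantification window
OFFSET_PROBS = np.array([0.01, 0.02, 0.05, 0.84, 0.05, 0.02, 0.01])
OFFSETS = np.arange(-3, 4)
#: decoy reads (outside the +/-3 window) as a fraction of each miRNA's count
DECOY_FRACTION = 0.05
DECOY_OFFSETS = (-5, 5)
#: fraction of offset-0 reads emitted as a 21-mer instead of a 22-mer
#: (same 5' end, trimmed 3' end), exercising the same-5'-end summation
SHORT_ISOFORM_FRACTION = 0.1

READ_LEN = 22
PRECURSOR_LEN = 80
_ARM_INTERVALS = {"5p": (8, 30), "3p": (50, 72)}


def _mirna_ids(cfg: SimConfig) -> list:
    return [f"mir-{i + 1:04d}" for i in range(cfg.n_mirna)]


def _gene_ids(cfg: SimConfig) -> list:
    return [f"g{i + 1:05d}" for i in range(cfg.n_genes)]


def make_loci(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Precursor loci per species, identical layout on each species'
    single synthetic chromosome (0-based half-open coordinates)."""
    loci = {sp: [] for sp in cfg.species()}
    ids = _mirna_ids(cfg)
    for i, mid in enumerate(ids):
        seq = "".join(rng.choice(list("ACGT"), PRECURSOR_LEN))
        arm = "5p" if i % 2 == 0 else "3p"
        strand = "+" if i % 3 != 2 else "-"
        ms, me = _ARM_INTERVALS[arm]
        start = 10_000 + i * 500
        for sp in cfg.species():
            loci[sp].append(
                MirnaLocus(
                    mirna_id=mid,
                    precursor_id=f"pre-{mid}",
                    species=sp,
                    precursor_seq=seq,
                    arm=arm,
                    mature_start0=ms,
                    mature_end0=me,
                    chrom="chr1",
                    strand=strand,
                    precursor_start0=start,
                )
            )
    return loci


#: relative branch lengths of the species tree ((human, chimp), macaque):
#: the human and chimpanzee terminal branches (~6-7 Myr) vs the macaque
#: lineage (~25-30 Myr).  DE implants are assigned to an up-species with
#: these weights, so expression divergence accumulates along the tree and
#: sample clustering sees a phylogenetic signal.
LINEAGE_BRANCH_WEIGHTS = (1.0, 1.0, 4.0)


def _abundance_and_de(cfg: SimConfig, rng: np.random.Generator):
    ids = _mirna_ids(cfg)
    w = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_mirna)
    p = w / w.sum()
    n_de = int(round(cfg.de_fraction * cfg.n_mirna))
    de_idx = rng.choice(cfg.n_mirna, size=n_de, replace=False)
    species = cfg.species()
    weights = np.array(
        [LINEAGE_BRANCH_WEIGHTS[i] if i < 3 else 1.0 for i in range(cfg.n_species)]
    )
    weights = weights / weights.sum()
    de = {}
    for i in sorted(de_idx):
        de[ids[i]] = species[rng.choice(cfg.n_species, p=weights)]
    return ids, p, de


def _sample_means(cfg: SimConfig, p: np.ndarray, ids: list, de: dict, species: str):
    mu = cfg.depth * p
    fold = np.array([cfg.de_fold if de.get(m) == species else 1.0 for m in ids])
    return mu * fold


def _nb_totals(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _draw_target_map(cfg: SimConfig, rng: np.random.Generator) -> dict:
    genes = _gene_ids(cfg)
    tmap = {}
    for mid in _mirna_ids(cfg):
        k = min(rng.poisson(cfg.target_density), cfg.n_genes)
        tmap[mid] = {str(g) for g in rng.choice(genes, size=k, replace=False)} if k else set()
    return tmap


def _read_seq(locus: MirnaLocus, genomic_offset: int, length: int) -> str:
    """Precursor subsequence whose genomic 5' position is
    ``mature_5p_genomic + genomic_offset`` (strand-aware)."""
    if locus.strand == "+":
        start = locus.mature_start0 + genomic_offset
    else:
        start = locus.mature_start0 - genomic_offset
    return locus.precursor_seq[start : start + length]


def simulate_read_stacks(cfg: SimConfig):
    """Generate per-sample read stacks, precursor loci and ground truth.

    Returns ``(stacks, loci, truth)`` where ``stacks`` is a list of
    :class:`ReadStack` (one per species x replicate), ``loci`` maps species
    to its :class:`MirnaLocus` list, and ``truth`` records the implanted DE
    miRNA, the true target map and the per-sample implanted copy number at
    each miRNA's mature 5' position.
    """
    cfg.validate()
    rng = cfg.stage_rng("reads")
    loci = make_loci(cfg, rng)
    ids, p, de = _abundance_and_de(cfg, rng)
    tmap = _draw_target_map(cfg, cfg.stage_rng("targets"))
    truth = GroundTruth(
        de_mirna={(m, sp) for m, sp in de.items()},
        target_map_true=tmap,
        sweep_windows_true=[(s, e) for s, e, _ in cfg.sweep_windows],
    )
    stacks = []
    for sp in cfg.species():
        mu = _sample_means(cfg, p, ids, de, sp)
        for rep in range(1, cfg.n_replicates + 1):
            sample_id = f"{sp}_rep{rep}"
            totals = _nb_totals(mu, cfg.nb_dispersion, rng)
            records = []
            site_counts = {}
            drawn = 0
            for locus, total in zip(loci[sp], totals):
                total = int(total)
                if total > 0:
                    per_offset = rng.multinomial(total, OFFSET_PROBS)
                    n_short = (
                        int(rng.binomial(per_offset[3], SHORT_ISOFORM_FRACTION))
                        if per_offset[3] > 0
                        else 0
                    )
                    site_counts[locus.mirna_id] = int(per_offset[3])
                    g5 = locus.mature_5p_genomic()
                    for off, n in zip(OFFSETS, per_offset):
                        n = int(n)
                        if off == 0:
                            n -= n_short
                        if n > 0:
                            records.append(
                                ReadRecord(
                                    _read_seq(locus, int(off), READ_LEN),
                                    locus.chrom,
                                    g5 + int(off),
                                    locus.strand,
                                    n,
                                )
                            )
                        if off == 0 and n_short > 0:
                            records.append(
                                ReadRecord(
                                    _read_seq(locus, 0, READ_LEN - 1),
                                    locus.chrom,
                                    g5,
                                    locus.strand,
                                    n_short,
                                )
                            )
                    drawn += total
                else:
                    site_counts[locus.mirna_id] = 0
                n_decoy = int(rng.poisson(DECOY_FRACTION * total)) if total > 0 else 0
                if n_decoy > 0:
                    n_left = int(rng.binomial(n_decoy, 0.5))
                    g5 = locus.mature_5p_genomic()
                    for off, n in zip(DECOY_OFFSETS, (n_left, n_decoy - n_left)):
                        if n > 0:
                            records.append(
                                ReadRecord(
                                    _read_seq(locus, off, READ_LEN),
                                    locus.chrom,
                                    g5 + off,
                                    locus.strand,
                                    n,
                                )
                            )
                    drawn += n_decoy
            truth.mature_site_counts[sample_id] = site_counts
            stacks.append(ReadStack(sample_id, sp, rep, records, drawn_total=drawn))
    return stacks, loci, truth


def simulate_counts(cfg: SimConfig):
    """Count-level shortcut: the same negative-binomial model as
    :func:`simulate_read_stacks`, skipping read placement.

    Returns ``(counts, meta, truth)``: a miRNA x sample DataFrame of
    totals, a sample metadata DataFrame (species, replicate), and the
    ground truth.  Used for large calibration studies where only the count
    matrix matters.
    """
    cfg.validate()
    rng = cfg.stage_rng("reads")
    ids, p, de = _abundance_and_de(cfg, rng)
    tmap = _draw_target_map(cfg, cfg.stage_rng("targets"))
    cols, data, meta = [], [], []
    for sp in cfg.species():
        mu = _sample_means(cfg, p, ids, de, sp)
        for rep in range(1, cfg.n_replicates + 1):
            cols.append(f"{sp}_rep{rep}")
            meta.append({"sample_id": f"{sp}_rep{rep}", "species": sp, "replicate": rep})
            data.append(_nb_totals(mu, cfg.nb_dispersion, rng))
    counts = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    counts.index.name = "mirna_id"
    truth = GroundTruth(
        de_mirna={(m, sp) for m, sp in de.items()},
        target_map_true=tmap,
        sweep_windows_true=[(s, e) for s, e, _ in cfg.sweep_windows],
    )
    return counts, pd.DataFrame(meta).set_index("sample_id"), truth


def simulate_expression(
    cfg: SimConfig,
    truth: GroundTruth,
    n_mrna_individuals: int = 5,
    n_protein_individuals: int = 4,
):
    """mRNA and protein expression matrices with implanted target shifts.

    True targets of a miRNA up-regulated in species A are shifted down by
    ``target_effect`` (log2 units) in species A; everything else is
    baseline plus Gaussian noise.  The mRNA matrix carries all species
    (the outgroup is needed for lineage classification); the protein
    matrix carries the ingroup pair only, mirroring the proteomics design.
    """
    cfg.validate()
    genes = _gene_ids(cfg)
    universe = set(genes)
    for mid, tset in truth.target_map_true.items():
        extra = tset - universe
        if extra:
            raise DimensionError(
                f"target map genes outside expression universe for {mid}: {sorted(extra)[:3]}"
            )
    rng = cfg.stage_rng("expression")
    shift = {sp: np.zeros(cfg.n_genes) for sp in cfg.species()}
    gene_idx = {g: i for i, g in enumerate(genes)}
    for mid, up_sp in sorted(truth.de_mirna):
        for g in sorted(truth.target_map_true.get(mid, ())):
            shift[up_sp][gene_idx[g]] -= cfg.target_effect

    def _matrix(species_list, n_ind, tag, noise_sd):
        base = rng.normal(8.0, 2.0, size=cfg.n_genes)
        cols, data = [], []
        for sp in species_list:
            for i in range(1, n_ind + 1):
                cols.append(f"{sp}_{tag}{i}")
                data.append(base + shift[sp] + rng.normal(0.0, noise_sd, cfg.n_genes))
        df = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
        df.index.name = "gene_id"
        return df

    mrna = _matrix(cfg.species(), n_mrna_individuals, "m", cfg.noise_sd)
    protein = _matrix(cfg.species()[:2], n_protein_individuals, "p", 2 * cfg.noise_sd)
    return mrna, protein


def simulate_transfection(
    cfg: SimConfig,
    truth: GroundTruth,
    mirna_id: str,
    cell_lines=("SH-SY5Y", "SK-N-SH"),
    mock_sd: float = 0.05,
):
    """Transfection log-ratios (mimic vs mock) for one miRNA.

    Columns are ``<cell line>:mock1`` / ``:mock2`` — the same mimic
    measurement referenced to two independent negative-control replicates,
    so the two columns share the gene- and cell-line-level signal and
    differ only by mock-specific noise.  True targets get mean effect
    ``-target_effect``.
    """
    cfg.validate()
    if mirna_id not in truth.target_map_true:
        raise KeyError(f"unknown miRNA id: {mirna_id!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(cfg.seed), STAGE_OFFSETS["transfection"]] + list(mirna_id.encode())
        )
    )
    genes = _gene_ids(cfg)
    is_target = np.array([g in truth.target_map_true[mirna_id] for g in genes])
    true_effect = np.where(is_target, -cfg.target_effect, 0.0)
    cols, data = [], []
    for cl in cell_lines:
        base = true_effect + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        for k in (1, 2):
            cols.append(f"{cl}:mock{k}")
            data.append(base + rng.normal(0.0, mock_sd, cfg.n_genes))
    df = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    df.index.name = "gene_id"
    return df


def simulate_target_predictions(
    cfg: SimConfig,
    truth: GroundTruth,
    algorithms=("algA", "algB", "algC"),
    sensitivity: float = 1.0,
    false_per_true: float = 1.0,
):
    """Per-algorithm predicted target maps: each algorithm keeps every true
    target with probability ``sensitivity`` and adds ``false_per_true``
    false predictions per true target, sampled from non-targets."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), STAGE_OFFSETS["targets"], 1]))
    genes = _gene_ids(cfg)
    maps = {}
    for alg in algorithms:
        amap = {}
        for mid in sorted(truth.target_map_true):
            true = sorted(truth.target_map_true[mid])
            kept = {g for g in true if rng.random() < sensitivity}
            n_false = int(round(false_per_true * len(true)))
            pool = sorted(set(genes) - set(true))
            false = (
                {str(g) for g in rng.choice(pool, size=min(n_false, len(pool)), replace=False)}
                if n_false
                else set()
            )
            amap[mid] = kept | false
        maps[alg] = amap
    return maps


def simulate_snp_track(cfg: SimConfig, precursors=None):
    """SNP track over the simulated region, with derived-allele excess
    implanted in the configured sweep windows.

    Returns ``(records, (n_derived, n_other))``; the totals are taken over
    the whole simulated track, which stands in for the genome in the
    window-vs-genome comparison of the scan.  Outside sweep windows the
    probability that a SNP classifies as human-derived (>=4 of 6 modern
    genomes derived, all Neanderthal alleles ancestral) equals
    ``background_derived_fraction``; inside, background plus the window's
    excess.
    """
    cfg.validate()
    sweeps = sorted(cfg.sweep_windows)
    for (s1, e1, _), (s2, e2, _) in zip(sweeps, sweeps[1:]):
        if s2 < e1:
            raise ConfigError(f"sweep windows overlap: [{s1},{e1}) and [{s2},{e2})")
    rng = cfg.stage_rng("snp")
    L = cfg.snp_region_length
    n = int(rng.poisson(cfg.snp_density * L))
    if n == 0:
        return [], (0, 0)
    positions = np.sort(rng.choice(L, size=min(n, L), replace=False))
    records = []
    n_derived = 0
    for pos in positions:
        p = cfg.background_derived_fraction
        for s, e, x in sweeps:
            if s <= pos < e:
                p += x
                break
        if rng.random() < p:
            rec = SnpRecord("chr1", int(pos), int(rng.integers(4, 7)), True)
            n_derived += 1
        else:
            modern = int(rng.integers(0, 7))
            nean = bool(rng.random() < 0.5) if modern < 4 else False
            rec = SnpRecord("chr1", int(pos), modern, nean)
        records.append(rec)
    return records, (n_derived, len(records) - n_derived)
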