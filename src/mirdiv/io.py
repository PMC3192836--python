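"""Readers and writers for the pipeline's plain-text formats.

Conventions: all genomic coordinates are 0-based half-open internally;
the BED-like SNP track is written natively in that convention.  Writers
emit a deterministic column order and Unix line endings, so identical
inputs produce bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SimConfig
from .datatypes import GroundTruth, MirnaLocus, ReadRecord, ReadStack, SnpRecord
from .errors import FormatError

STACK_COLUMNS = ["sequence", "chrom", "pos0", "strand", "copies"]
ANNOT_COLUMNS = [
    "mirna_id", "precursor_id", "species", "arm",
    "mat_start0", "mat_end0", "chrom", "strand", "precursor_start0",
]
SNP_COLUMNS = ["chrom", "pos0", "end0", "derived_count_of_6", "neanderthal_all_ancestral"]


def _err(path, lineno, msg):
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# read stacks

def write_read_stack(stack: ReadStack, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# sample_id={stack.sample_id}\tspecies={stack.species}"
                 f"\treplicate={stack.replicate}\tdrawn_total={stack.drawn_total}\n")
        fh.write("\t".join(STACK_COLUMNS) + "\n")
        for r in stack.records:
            fh.write(f"{r.sequence}\t{r.chrom}\t{r.pos0}\t{r.strand}\t{r.copies}\n")


def read_read_stack(path) -> ReadStack:
    path = Path(path)
    meta = {}
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].startswith("#"):
        for kv in lines[0][1:].strip().split("\t"):
            k, _, v = kv.partition("=")
            meta[k.strip()] = v
        start = 1
    if start >= len(lines) or lines[start].split("\t") != STACK_COLUMNS:
        _err(path, start + 1, f"expected header {STACK_COLUMNS}")
    for i, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            _err(path, i, f"expected 5 fields, got {len(parts)}")
        try:
            rec = ReadRecord(parts[0], parts[1], int(parts[2]), parts[3], int(parts[4]))
        except ValueError as e:
            _err(path, i, str(e))
        records.append(rec)
    return ReadStack(
        sample_id=meta.get("sample_id", path.stem),
        species=meta.get("species", ""),
        replicate=int(meta.get("replicate", 0)),
        records=records,
        drawn_total=int(meta.get("drawn_total", 0)),
    )


# ---------------------------------------------------------------------------
# precursors: FASTA + annotation TSV

def write_precursors(loci, fasta_path, annot_path) -> None:
    seen = set()
    seqs = []
    rows = []
    for lc in loci:
        key = (lc.precursor_id, lc.species)
        if key not in seen:
            seen.add(key)
            seqs.append(SeqRecord(Seq(lc.precursor_seq),
                                  id=f"{lc.species}|{lc.precursor_id}", description=""))
        rows.append([lc.mirna_id, lc.precursor_id, lc.species, lc.arm,
                     lc.mature_start0, lc.mature_end0, lc.chrom, lc.strand,
                     lc.precursor_start0])
    SeqIO.write(seqs, fasta_path, "fasta")
    pd.DataFrame(rows, columns=ANNOT_COLUMNS).to_csv(annot_path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """FASTA to {record id: sequence string}."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def read_precursors(fasta_path, annot_path) -> list:
    seqs = read_fasta(fasta_path)
    annot = pd.read_csv(annot_path, sep="\t")
    missing = set(ANNOT_COLUMNS) - set(annot.columns)
    if missing:
        raise FormatError(f"{annot_path}: missing column(s) {sorted(missing)}")
    loci = []
    for _, row in annot.iterrows():
        key = f"{row['species']}|{row['precursor_id']}"
        if key not in seqs:
            raise FormatError(f"{annot_path}: precursor {key!r} absent from {fasta_path}")
        loci.append(MirnaLocus(
            mirna_id=row["mirna_id"], precursor_id=row["precursor_id"],
            species=row["species"], precursor_seq=seqs[key], arm=row["arm"],
            mature_start0=int(row["mat_start0"]), mature_end0=int(row["mat_end0"]),
            chrom=row["chrom"], strand=row["strand"],
            precursor_start0=int(row["precursor_start0"]),
        ))
    return loci


# ---------------------------------------------------------------------------
# labeled matrices (counts, expression, transfection)

def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate row id {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise FormatError(f"{path}: duplicate column id {dupc[0]!r}")
    return df


# ---------------------------------------------------------------------------
# SNP track (BED-like)

def write_bed_snps(records, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos0}\t{r.pos0 + 1}\t"
                     f"{r.derived_count_of_modern}\t{int(r.neanderthal_all_ancestral)}\n")


def read_bed_snps(path) -> list:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != SNP_COLUMNS:
        _err(path, 1, f"expected header {SNP_COLUMNS}")
    out = []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            _err(path, i, f"expected 5 fields, got {len(parts)}")
        chrom, pos0, end0, dcount, nean = parts
        pos0, end0 = int(pos0), int(end0)
        if end0 != pos0 + 1:
            _err(path, i, f"end column must equal pos0+1, got {end0} vs {pos0}+1")
        try:
            rec = SnpRecord(chrom, pos0, int(dcount), bool(int(nean)))
        except ValueError as e:
            _err(path, i, str(e))
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# target maps, ground truth, config

def write_target_map(maps: dict, path) -> None:
    """``maps``: {algorithm: {mirna_id: gene set}} to a long TSV."""
    rows = []
    for alg in sorted(maps):
        for mid in sorted(maps[alg]):
            for g in sorted(maps[alg][mid]):
                rows.append([alg, mid, g])
    pd.DataFrame(rows, columns=["algorithm", "mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_target_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    missing = {"algorithm", "mirna_id", "gene_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    maps = {}
    for alg, mid, g in df.itertuples(index=False):
        maps.setdefault(alg, {}).setdefault(mid, set()).add(g)
    return maps


def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "de_mirna": sorted([list(x) for x in truth.de_mirna]),
        "target_map_true": {m: sorted(g) for m, g in sorted(truth.target_map_true.items())},
        "sweep_windows_true": [list(w) for w in truth.sweep_windows_true],
    }
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return GroundTruth(
        de_mirna={tuple(x) for x in doc.get("de_mirna", [])},
        target_map_true={m: set(g) for m, g in doc.get("target_map_true", {}).items()},
        sweep_windows_true=[tuple(w) for w in doc.get("sweep_windows_true", [])],
    )


def load_config(path) -> SimConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(doc)


def write_newick(dendrogram, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(dendrogram.newick() + "\n")


# ---------------------------------------------------------------------------
# run manifest

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, seed, config: SimConfig = None, inputs=()) -> dict:
    from . import __version__

    manifest = {
        "seed": int(seed),
        "package_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest() if config is not None else None,
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
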