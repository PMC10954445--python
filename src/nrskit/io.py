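"""Plain-text format round-tripping: FASTA, BED, TSV, VCF, YAML config.

All coordinates are 0-based half-open internally; VCF is the only
1-based surface.  Every writer stamps a provenance comment/header line.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genotyping import GT_CODES, GT_STRINGS, GenotypeMatrix
from .merging import NrsCatalogue
from .reference import Gene, ReferenceGenome

PROVENANCE = f"nrskit {__version__}"


# ----------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fai(path: str | Path) -> None:
    """Create a .fai index next to a FASTA file."""
    from pyfaidx import Faidx
    Faidx(str(path))


# ------------------------------------------------------------------- BED

def write_bed(path: str | Path,
              intervals: Iterable[tuple],
              header: bool = False) -> None:
    """Rows are (chrom, start, end[, name[, score]]); 0-based half-open."""
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {PROVENANCE}\n")
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            row = [fields[0], int(fields[1]), int(fields[2])] + fields[3:]
            out.append(tuple(row))
    return out


# ------------------------------------------------------------------- TSV

def write_tsv(path: str | Path, frame: pd.DataFrame,
              index: bool = False) -> None:
    with open(path, "w") as handle:
        handle.write(f"# {PROVENANCE}\n")
        frame.to_csv(handle, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ------------------------------------------------------------------- VCF

@dataclass
class VcfRecord:
    chrom: str
    pos: int                 # 1-based
    id: str
    ref: str
    alt: str
    qual: str = "."
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)  # sample -> GT


def _format_info(info: Mapping) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        parts.append(key if value is True else f"{key}={value}")
    return ";".join(parts)


def _parse_info(text: str) -> dict:
    if text == ".":
        return {}
    out: dict = {}
    for part in text.split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
        else:
            out[part] = True
    return out


def write_vcf(path: str | Path, records: Sequence[VcfRecord],
              samples: Sequence[str] = (),
              contigs: Mapping[str, int] | None = None,
              extra_headers: Sequence[str] = ()) -> None:
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##source={PROVENANCE}\n")
        for name, length in (contigs or {}).items():
            handle.write(f"##contig=<ID={name},length={length}>\n")
        for line in extra_headers:
            handle.write(line.rstrip("\n") + "\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
        columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO"]
        if samples:
            columns += ["FORMAT", *samples]
        handle.write("\t".join(columns) + "\n")
        for rec in records:
            fields = [rec.chrom, str(rec.pos), rec.id, rec.ref, rec.alt,
                      rec.qual, rec.filter, _format_info(rec.info)]
            if samples:
                fields.append("GT")
                fields += [rec.genotypes.get(s, "./.") for s in samples]
            handle.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VcfRecord], list[str]]:
    """Parse a plain-text VCF; malformed lines raise with line numbers."""
    records: list[VcfRecord] = []
    samples: list[str] = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) > 9:
                    samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >=8 VCF columns, got "
                    f"{len(fields)}")
            try:
                pos = int(fields[1])
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: bad POS field {fields[1]!r}"
                ) from err
            genotypes: dict[str, str] = {}
            if len(fields) > 9:
                fmt_keys = fields[8].split(":")
                gt_index = fmt_keys.index("GT") if "GT" in fmt_keys else 0
                for sample, value in zip(samples, fields[9:]):
                    genotypes[sample] = value.split(":")[gt_index]
            records.append(VcfRecord(
                chrom=fields[0], pos=pos, id=fields[2], ref=fields[3],
                alt=fields[4], qual=fields[5], filter=fields[6],
                info=_parse_info(fields[7]), genotypes=genotypes))
    return records, samples


# ----------------------------------------------- reference round-tripping

def write_reference(ref: ReferenceGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fa", ref.sequences)
    write_fai(outdir / "reference.fa")
    write_bed(outdir / "satellites.bed",
              [(c, s, e, name) for c, s, e, name in ref.satellites])
    write_bed(outdir / "arms.bed",
              [(c, s, e, "centromere") for c, (s, e) in ref.arms.items()])
    rows = []
    for g in ref.genes:
        exons = ",".join(f"{s}-{e}" for s, e in g.exons)
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                     "start": g.start, "end": g.end, "strand": g.strand,
                     "tss": g.tss, "exons": exons, "coding": g.coding})
    write_tsv(outdir / "genes.tsv", pd.DataFrame(rows))


def read_reference(outdir: str | Path) -> ReferenceGenome:
    outdir = Path(outdir)
    sequences = read_fasta(outdir / "reference.fa")
    satellites = [(c, s, e, n) for c, s, e, n
                  in read_bed(outdir / "satellites.bed")]
    arms = {c: (s, e) for c, s, e, _ in read_bed(outdir / "arms.bed")}
    genes = []
    frame = read_tsv(outdir / "genes.tsv")
    for _, row in frame.iterrows():
        exons = tuple(tuple(int(x) for x in part.split("-"))
                      for part in str(row["exons"]).split(","))
        genes.append(Gene(gene_id=row["gene_id"], chrom=row["chrom"],
                          start=int(row["start"]), end=int(row["end"]),
                          strand=row["strand"], exons=exons,
                          coding=bool(row["coding"])))
    return ReferenceGenome(sequences=sequences, arms=arms,
                           satellites=satellites, genes=genes)


# ----------------------------------------------- catalogue round-tripping

def catalogue_to_vcf(catalogue: NrsCatalogue, ref: ReferenceGenome,
                     path: str | Path,
                     genotypes: GenotypeMatrix | None = None) -> None:
    """Placed records as insertion VCF (ALT carries the full sequence)."""
    records = []
    samples = genotypes.samples if genotypes is not None else []
    for rec in catalogue.placed_records:
        anchor_base = (ref.sequences[rec.chrom][rec.position - 1]
                       if rec.position > 0 else "N")
        info = {"GNRS": rec.gnrs_id, "SUPP": len(rec.samples)}
        if rec.af is not None:
            info["AF"] = f"{rec.af:.6g}"
        if rec.category:
            info["CATEGORY"] = rec.category
        if rec.multi_allelic:
            info["MULTIALLELIC"] = True
        gts = {}
        if genotypes is not None and rec.gnrs_id in genotypes.dosage.index:
            for s in samples:
                gts[s] = GT_STRINGS[int(genotypes.dosage.at[rec.gnrs_id, s])]
        records.append(VcfRecord(
            chrom=rec.chrom, pos=rec.position,   # pos of base before insert
            id=rec.gnrs_id, ref=anchor_base,
            alt=anchor_base + rec.sequence, info=info, genotypes=gts))
    write_vcf(path, records, samples=samples,
              contigs=ref.chrom_lengths)


def vcf_to_genotypes(path: str | Path) -> GenotypeMatrix:
    records, samples = read_vcf(path)
    table = {}
    for rec in records:
        locus = rec.info.get("GNRS", rec.id)
        table[locus] = {s: GT_CODES.get(rec.genotypes.get(s, "./."), -1)
                        for s in samples}
    frame = pd.DataFrame(table).T.astype("int8")
    return GenotypeMatrix(dosage=frame[list(samples)] if samples else frame)


def unplaced_to_fasta(catalogue: NrsCatalogue, path: str | Path) -> None:
    write_fasta(path, {r.gnrs_id: r.sequence
                       for r in catalogue.unplaced_records})


# ---------------------------------------------------------------- config

def load_config(path: str | Path, known_keys: set[str]) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    unknown = set(data) - known_keys
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return data
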