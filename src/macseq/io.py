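"""Readers and writers for the standard formats at the package boundary.

Internal coordinates are 0-based half-open everywhere; conversions to
1-based (VCF, GFF3) happen only here.  FASTA goes through Biopython;
VCF is written as plain VCF 4.2 text and read back through pysam.
Malformed records raise :class:`ParseError` carrying the line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationSet, Transcript
from .simulate.reference import ReferenceAssembly

__all__ = ["ParseError",
           "write_fasta", "read_fasta",
           "write_bedgraph", "read_bedgraph",
           "write_bed", "read_bed",
           "write_gff3", "read_gff3",
           "write_vcf", "read_vcf",
           "write_pileup", "read_pileup",
           "write_matepairs", "read_matepairs",
           "write_reference", "read_reference"]

_BASES = "ACGT"


class ParseError(ValueError):
    """A malformed record, with the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


# -- FASTA ----------------------------------------------------------------

def write_fasta(path, chroms: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in chroms.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# -- bedGraph (QV track, run-length encoded) ------------------------------

def write_bedgraph(path, tracks: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            v = np.asarray(values)
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(v[s])}\n")


def read_bedgraph(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(L, dtype=np.int16) for c, L in lengths.items()}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ParseError(path, i, f"expected 4 fields, got {len(f)}")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), int(float(f[3]))
            if chrom not in out:
                raise ParseError(path, i, f"unknown chromosome {chrom!r}")
            if not 0 <= s < e <= len(out[chrom]):
                raise ParseError(path, i, f"interval [{s},{e}) out of bounds")
            out[chrom][s:e] = v
    return out


# -- BED ------------------------------------------------------------------

def write_bed(path, intervals: dict[str, np.ndarray],
              names: dict[str, list[str]] | None = None) -> None:
    with open(path, "w") as fh:
        for chrom, arr in intervals.items():
            for i, (s, e) in enumerate(np.asarray(arr).reshape(-1, 2)):
                if names:
                    fh.write(f"{chrom}\t{s}\t{e}\t{names[chrom][i]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> dict[str, np.ndarray]:
    rows: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(path, i, "fewer than 3 BED fields")
            try:
                s, e = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
            if e < s:
                raise ParseError(path, i, f"end {e} < start {s}")
            rows.setdefault(f[0], []).append([s, e])
    return {c: np.array(v, dtype=np.int64) for c, v in rows.items()}


# -- GFF3 gene models ------------------------------------------------------

def write_gff3(path, annotation: AnnotationSet) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for t in annotation.transcripts:
            s, e = t.span
            fh.write(f"{t.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                     f"ID={t.gene_id}\n")
            fh.write(f"{t.chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                     f"ID={t.tx_id};Parent={t.gene_id}\n")
            for (xs, xe) in t.exons:
                fh.write(f"{t.chrom}\t.\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t"
                         f"Parent={t.tx_id}\n")
            cds = list(t.cds) if t.strand == "+" else list(t.cds)[::-1]
            done = 0
            for (cs, ce) in cds:
                phase = (3 - done % 3) % 3
                fh.write(f"{t.chrom}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t"
                         f"{phase}\tParent={t.tx_id}\n")
                done += ce - cs


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> AnnotationSet:
    lengths: dict[str, int] = {}
    mrna: dict[str, dict] = {}
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                f = line.split()
                lengths[f[1]] = int(f[3])
                continue
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(path, i, f"expected 9 fields, got {len(f)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
            if chrom in lengths and not 0 <= s < e <= lengths[chrom]:
                raise ParseError(path, i, f"feature [{s},{e}) out of bounds "
                                          f"for {chrom} (length {lengths[chrom]})")
            a = _gff_attrs(attrs)
            if ftype == "mRNA":
                tid = a.get("ID")
                if tid is None:
                    raise ParseError(path, i, "mRNA without ID")
                mrna[tid] = {"chrom": chrom, "strand": strand,
                             "gene": a.get("Parent", tid)}
                order.append(tid)
            elif ftype == "exon":
                exons.setdefault(a.get("Parent"), []).append((s, e))
            elif ftype == "CDS":
                cds.setdefault(a.get("Parent"), []).append((s, e))
    transcripts = []
    for tid in order:
        m = mrna[tid]
        transcripts.append(Transcript(
            tx_id=tid, gene_id=m["gene"], chrom=m["chrom"], strand=m["strand"],
            exons=tuple(sorted(exons.get(tid, []))),
            cds=tuple(sorted(cds.get(tid, [])))))
    return AnnotationSet(transcripts, lengths)


# -- VCF -------------------------------------------------------------------

def write_vcf(path, calls: pd.DataFrame, lengths: dict[str, int] | None = None,
              sample: str = "sample") -> None:
    """Write variant calls (het/hom_alt rows) as VCF 4.2 with GT:DP:GQ."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in (lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for row in calls.itertuples():
            gt = "0/1" if row.zygosity == "het" else "1/1"
            qv = int(round(row.call_qv))
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t"
                     f"{qv}\t.\t.\tGT:DP:GQ\t{gt}:{int(row.depth)}:{qv}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF back into the internal call schema."""
    import pysam

    rows = {k: [] for k in ("chrom", "pos", "ref", "alt", "zygosity",
                            "call_qv", "depth")}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            s = rec.samples[0]
            gt = s.get("GT")
            zyg = "het" if len(set(gt)) > 1 else ("hom_alt" if gt[0] == 1 else "hom_ref")
            rows["chrom"].append(rec.chrom)
            rows["pos"].append(rec.pos - 1)
            rows["ref"].append(rec.ref)
            rows["alt"].append(rec.alts[0] if rec.alts else None)
            rows["zygosity"].append(zyg)
            rows["call_qv"].append(float(rec.qual) if rec.qual is not None else 0.0)
            rows["depth"].append(int(s.get("DP") or 0))
    return pd.DataFrame(rows)


# -- TSV tables ------------------------------------------------------------

_PILEUP_COLS = ["chrom", "pos1", "ref", "ref_qv", "depth", "nA", "nC", "nG", "nT"]


def write_pileup(path, pileup: pd.DataFrame) -> None:
    """Write the pileup evidence schema (1-based positions on disk)."""
    out = pd.DataFrame({
        "chrom": pileup["chrom"],
        "pos1": pileup["pos"] + 1,
        "ref": [_BASES[c] for c in pileup["ref_code"]],
        "ref_qv": pileup["ref_qv"], "depth": pileup["depth"],
        "nA": pileup["nA"], "nC": pileup["nC"],
        "nG": pileup["nG"], "nT": pileup["nT"]})
    out.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing pileup columns {sorted(missing)}")
    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos1"] - 1,
        "ref_code": [_BASES.index(b) for b in df["ref"]],
        "ref_qv": df["ref_qv"], "depth": df["depth"],
        "nA": df["nA"], "nC": df["nC"], "nG": df["nG"], "nT": df["nT"]})


def write_matepairs(path, pairs: pd.DataFrame) -> None:
    pairs.to_csv(path, sep="\t", index=False,
                 columns=["chrom", "pos1", "pos2", "span", "congruent", "library"])


def read_matepairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["congruent"] = df["congruent"].astype(bool)
    return df


# -- reference bundle ------------------------------------------------------

def write_reference(prefix, ref: ReferenceAssembly) -> dict[str, Path]:
    """Write a reference assembly as FASTA + QV bedGraph + gap/repeat BED."""
    prefix = Path(prefix)
    paths = {
        "fasta": prefix.with_suffix(".fa"),
        "qv": prefix.parent / (prefix.name + ".qv.bedgraph"),
        "gaps": prefix.parent / (prefix.name + ".gaps.bed"),
        "repeats": prefix.parent / (prefix.name + ".repeats.bed"),
    }
    write_fasta(paths["fasta"], ref.chroms)
    write_bedgraph(paths["qv"], ref.qv)
    write_bed(paths["gaps"], ref.gaps)
    write_bed(paths["repeats"], ref.repeats)
    return paths


def read_reference(prefix) -> ReferenceAssembly:
    prefix = Path(prefix)
    chroms = read_fasta(prefix.with_suffix(".fa"))
    lengths = {c: len(s) for c, s in chroms.items()}
    qv = read_bedgraph(prefix.parent / (prefix.name + ".qv.bedgraph"), lengths)
    gaps = read_bed(prefix.parent / (prefix.name + ".gaps.bed"))
    repeats = read_bed(prefix.parent / (prefix.name + ".repeats.bed"))
    empty = np.empty((0, 2), dtype=np.int64)
    return ReferenceAssembly(
        chroms, qv,
        {c: gaps.get(c, empty) for c in chroms},
        {c: repeats.get(c, empty) for c in chroms})
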