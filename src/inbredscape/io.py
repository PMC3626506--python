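"""Core data containers and file I/O.

All in-memory coordinates are 0-based, half-open.  File formats keep their
native conventions: GFF3 and VCF are 1-based (inclusive), BED is 0-based
half-open.  Conversions happen only at read/write time.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Assembly:
    """A named collection of scaffold sequences; the coordinate frame for
    every annotation downstream."""

    sequences: dict[str, str]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def callable_bases(self) -> int:
        """Non-N bases: the denominator used for genome-wide rates."""
        return sum(len(s) - s.count("N") - s.count("n") for s in self.sequences.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        return self.sequences[name][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Assembly":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=n, description="") for n, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")


_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype"]


@dataclass
class VariantSet:
    """Heterozygous SNPs and short InDels against one assembly.

    ``df`` columns: chrom, pos (0-based), ref, alt, vtype ('SNP' | 'INDEL').
    Every record represents one heterozygous site (genotype 0/1);
    multi-allelic records collapse to one site.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _VARIANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"VariantSet missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snps(self) -> pd.DataFrame:
        return self.df[self.df.vtype == "SNP"]

    @property
    def indels(self) -> pd.DataFrame:
        return self.df[self.df.vtype == "INDEL"]

    @classmethod
    def empty(cls) -> "VariantSet":
        return cls(pd.DataFrame(columns=_VARIANT_COLUMNS).astype({"pos": np.int64}))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "VariantSet":
        df = pd.DataFrame(records, columns=_VARIANT_COLUMNS)
        return cls(df)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "VariantSet":
        from cyvcf2 import VCF

        rows = []
        for v in VCF(str(path)):
            alt = v.ALT[0] if v.ALT else v.REF
            vtype = "SNP" if len(v.REF) == 1 and len(alt) == 1 else "INDEL"
            rows.append((v.CHROM, v.POS - 1, v.REF, alt, vtype))
        if not rows:
            return cls.empty()
        return cls.from_records(rows)

    def to_vcf(self, path: str | Path, assembly: Assembly | None = None) -> None:
        """Write a minimal VCF 4.2 with 1-based positions and het genotypes."""
        buf = _io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if assembly is not None:
            for name in assembly.names:
                buf.write(f"##contig=<ID={name},length={assembly.length(name)}>\n")
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        df = self.df.sort_values(["chrom", "pos"], kind="stable")
        for row in df.itertuples(index=False):
            buf.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t0/1\n")
        Path(path).write_text(buf.getvalue())


@dataclass
class AnnotationSet:
    """Gene models plus repeat intervals, all 0-based half-open.

    genes: gene_id, chrom, start, end, strand
    exons: gene_id, chrom, start, end
    cds:   gene_id, chrom, start, end, phase
    tes:   copy_id, chrom, start, end, family
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand"]))
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]))
    cds: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "phase"]))
    tes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["copy_id", "chrom", "start", "end", "family"]))

    def gene_cds(self, gene_id: str) -> pd.DataFrame:
        return self.cds[self.cds.gene_id == gene_id].sort_values("start")

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes.itertuples(index=False):
            lines.append("\t".join([g.chrom, "inbredscape", "gene", str(g.start + 1),
                                    str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"]))
            mrna = f"{g.gene_id}.t1"
            lines.append("\t".join([g.chrom, "inbredscape", "mRNA", str(g.start + 1),
                                    str(g.end), ".", g.strand, ".",
                                    f"ID={mrna};Parent={g.gene_id}"]))
            for e in self.exons[self.exons.gene_id == g.gene_id].itertuples(index=False):
                lines.append("\t".join([g.chrom, "inbredscape", "exon", str(e.start + 1),
                                        str(e.end), ".", g.strand, ".", f"Parent={mrna}"]))
            for c in self.gene_cds(g.gene_id).itertuples(index=False):
                lines.append("\t".join([g.chrom, "inbredscape", "CDS", str(c.start + 1),
                                        str(c.end), ".", g.strand, str(c.phase),
                                        f"Parent={mrna}"]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationSet":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        mrna_to_gene: dict[str, str] = {}
        for m in db.features_of_type("mRNA"):
            mrna_to_gene[m.id] = (m.attributes.get("Parent") or [m.id])[0]
        genes, exons, cds = [], [], []
        for g in db.features_of_type("gene"):
            genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
        for ftype, sink in (("exon", exons), ("CDS", cds)):
            for f in db.features_of_type(ftype):
                parent = (f.attributes.get("Parent") or [""])[0]
                gid = mrna_to_gene.get(parent, parent)
                if ftype == "exon":
                    sink.append((gid, f.seqid, f.start - 1, f.end))
                else:
                    phase = 0 if f.frame in (".", None) else int(f.frame)
                    sink.append((gid, f.seqid, f.start - 1, f.end, phase))
        out = cls()
        if genes:
            out.genes = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
        if exons:
            out.exons = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"])
        if cds:
            out.cds = pd.DataFrame(cds, columns=["gene_id", "chrom", "start", "end", "phase"])
        return out


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-like TSV; first three columns chrom/start/end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if names is not None:
        cols[: len(names) + 3][3:] = names[: df.shape[1] - 3]
        cols = ["chrom", "start", "end"] + names[: df.shape[1] - 3]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


_HIT_COLUMNS = ["query_id", "query_class", "scaffold", "start", "end",
                "strand", "identity", "query_coverage"]


def hit_table(rows: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Normalise retroviral-homology hits into the standard HitTable frame.

    Columns: query_id, query_class (gag|pol|env|LTR|genome), scaffold,
    start, end (0-based half-open), strand, identity and query_coverage
    in [0, 1].
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return df


def read_hits_outfmt6(path: str | Path, query_meta: Mapping[str, tuple[str, int]]) -> pd.DataFrame:
    """Read BLAST outfmt-6-like hits.

    ``query_meta`` maps query_id -> (query_class, query_length); the extra
    length column is needed because outfmt 6 reports alignment spans, not
    query coverage.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    raw = pd.read_csv(path, sep="\t", header=None, names=cols)
    rows = []
    for r in raw.itertuples(index=False):
        qclass, qlen = query_meta[r.qseqid]
        sstart, send = sorted((int(r.sstart), int(r.send)))
        strand = "+" if r.sstart <= r.send else "-"
        coverage = (abs(r.qend - r.qstart) + 1) / qlen
        rows.append((r.qseqid, qclass, r.sseqid, sstart - 1, send, strand,
                     r.pident / 100.0, min(coverage, 1.0)))
    return hit_table(rows)
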