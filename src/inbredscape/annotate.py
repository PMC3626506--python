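"""Variant classification: genomic compartment, coding effect, Ts/Tv.

Compartment precedence is exon > intron > intergenic: a variant
overlapping any exon is exonic; otherwise, if it falls inside a gene
span it is intronic; everything else is intergenic.  Coding effects are
computed on the coding strand via the standard genetic code, so
minus-strand genes are handled by reverse complementation of the
spliced CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import Assembly, AnnotationSet, VariantSet, revcomp

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chrom merged intervals as an (n, 2) array, sorted by start."""
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _covers(intervals: dict[str, np.ndarray], chrom: str, pos: int) -> bool:
    iv = intervals.get(chrom)
    if iv is None or iv.size == 0:
        return False
    i = int(np.searchsorted(iv[:, 0], pos, "right")) - 1
    return i >= 0 and pos < iv[i, 1]


def merged_length(df: pd.DataFrame) -> int:
    """Total bases covered by a set of (possibly overlapping) intervals."""
    return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in _merge_intervals(df).values()))


def classify_compartment(variants: VariantSet, annotation: AnnotationSet) -> pd.Series:
    """Label each variant exon / intron / intergenic (exon wins overlaps)."""
    exons = _merge_intervals(annotation.exons) if len(annotation.exons) else {}
    genes = _merge_intervals(annotation.genes) if len(annotation.genes) else {}
    labels = []
    for v in variants.df.itertuples(index=False):
        if _covers(exons, v.chrom, v.pos):
            labels.append("exon")
        elif _covers(genes, v.chrom, v.pos):
            labels.append("intron")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=variants.df.index, name="compartment")


@dataclass
class CDSModel:
    """Spliced coding model of one gene: ordered genomic CDS segments,
    strand and the phase of the first translated segment."""

    gene_id: str
    chrom: str
    segments: list[tuple[int, int]]  # sorted by genomic start
    strand: str
    phase: int = 0

    @classmethod
    def from_annotation(cls, annotation: AnnotationSet, gene_id: str) -> "CDSModel":
        seg = annotation.gene_cds(gene_id)
        if seg.empty:
            raise ValueError(f"gene {gene_id} has no CDS")
        gene = annotation.genes[annotation.genes.gene_id == gene_id].iloc[0]
        segs = [(int(s), int(e)) for s, e in zip(seg.start, seg.end)]
        first = seg.iloc[0] if gene.strand == "+" else seg.iloc[-1]
        return cls(gene_id=gene_id, chrom=gene.chrom, segments=segs,
                   strand=gene.strand, phase=int(first.phase))

    def spliced(self, assembly: Assembly) -> str:
        s = "".join(assembly.fetch(self.chrom, a, b) for a, b in self.segments)
        return revcomp(s) if self.strand == "-" else s

    def cds_offset(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based offset in the spliced CDS
        (coding-strand orientation); None when outside every segment."""
        off = 0
        total = sum(b - a for a, b in self.segments)
        for a, b in self.segments:
            if a <= pos < b:
                plus_off = off + (pos - a)
                return plus_off if self.strand == "+" else total - 1 - plus_off
            off += b - a
        return None

    def contains(self, pos: int) -> bool:
        return self.cds_offset(pos) is not None


def coding_effect(pos: int, ref: str, alt: str, model: CDSModel,
                  assembly: Assembly) -> str:
    """Effect of a SNP on the encoded protein.

    Returns 'synonymous', 'nonsynonymous', 'stop_gained', or 'none' when
    the site lies outside the CDS (e.g. UTR exon).  The reference allele
    is checked against the assembly; a mismatch is a hard error because
    it means the VCF and FASTA disagree.
    """
    genome_base = assembly.fetch(model.chrom, pos, pos + 1)
    if genome_base != ref:
        raise ValueError(
            f"reference allele {ref} at {model.chrom}:{pos} does not match "
            f"assembly base {genome_base}")
    off = model.cds_offset(pos)
    if off is None:
        return "none"
    mrna = model.spliced(assembly)[model.phase:]
    off -= model.phase
    if off < 0 or off >= len(mrna) - len(mrna) % 3:
        return "none"
    codon_i, within = divmod(off, 3)
    codon = mrna[codon_i * 3: codon_i * 3 + 3]
    alt_coding = alt if model.strand == "+" else revcomp(alt)
    new_codon = codon[:within] + alt_coding + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    return "nonsynonymous"


def indel_cds_effect(pos: int, ref: str, alt: str, model: CDSModel) -> str:
    """frameshift / inframe / none for an InDel against one CDS model.

    The frame test uses the length of the InDel that actually overlaps
    CDS: a deletion spanning a CDS boundary contributes only its
    overlapping bases.
    """
    if len(ref) > len(alt):  # deletion: bases after the anchor are removed
        del_start, del_end = pos + len(alt), pos + len(ref)
        overlap = 0
        for a, b in model.segments:
            overlap += max(0, min(del_end, b) - max(del_start, a))
        if overlap == 0:
            return "none"
        return "frameshift" if overlap % 3 else "inframe"
    elif len(alt) > len(ref):  # insertion between pos and pos+1
        ins_len = len(alt) - len(ref)
        inside = any(a <= pos < b - 1 for a, b in model.segments)
        if not inside:
            return "none"
        return "frameshift" if ins_len % 3 else "inframe"
    return "none"


def ts_tv(snps) -> float:
    """Transition/transversion ratio of single-base substitutions.

    Accepts a VariantSet, a DataFrame with ref/alt columns, or an
    iterable of (ref, alt) pairs.  Multi-nucleotide substitutions are
    excluded.  Zero transversions yields +inf with a warning.
    """
    if isinstance(snps, VariantSet):
        pairs = list(zip(snps.snps.ref, snps.snps.alt))
    elif isinstance(snps, pd.DataFrame):
        pairs = list(zip(snps.ref, snps.alt))
    else:
        pairs = list(snps)
    ts = tv = 0
    for ref, alt in pairs:
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            continue
        if (ref, alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        warnings.warn("no transversions observed; Ts/Tv ratio is infinite")
        return float("inf")
    return ts / tv


def classify_variants(variants: VariantSet, annotation: AnnotationSet,
                      assembly: Assembly) -> pd.DataFrame:
    """Full per-variant classification: compartment plus coding effect."""
    df = variants.df.copy()
    df["compartment"] = classify_compartment(variants, annotation)
    models = {}
    cds_by_chrom = {}
    if len(annotation.cds):
        for gid in annotation.cds.gene_id.unique():
            m = CDSModel.from_annotation(annotation, gid)
            models[gid] = m
            cds_by_chrom.setdefault(m.chrom, []).append(m)
    effects = []
    for v in df.itertuples(index=False):
        effect = "none"
        if v.compartment == "exon":
            for m in cds_by_chrom.get(v.chrom, []):
                lo = min(a for a, _ in m.segments)
                hi = max(b for _, b in m.segments)
                if not (lo <= v.pos < hi):
                    continue
                if v.vtype == "SNP":
                    if m.contains(v.pos):
                        effect = coding_effect(v.pos, v.ref, v.alt, m, assembly)
                else:
                    effect = indel_cds_effect(v.pos, v.ref, v.alt, m)
                if effect != "none":
                    break
        effects.append(effect)
    df["coding_effect"] = effects
    return df


def percent_of_genome(feature_bases: float, assembly_bases: float, ndigits: int = 1) -> float:
    """Percentage of the assembly covered by a feature class, rounded the
    way genome-report tables print it (one decimal by default)."""
    if assembly_bases <= 0:
        raise ValueError("assembly length must be positive")
    return round(100.0 * feature_bases / assembly_bases, ndigits)


def annotation_summary(classified: pd.DataFrame, annotation: AnnotationSet,
                       assembly: Assembly) -> dict:
    """Consolidated variant-annotation statistics.

    Returns per-compartment SNP counts and rates (count / compartment
    length), Ts/Tv, the synonymous:nonsynonymous ratio, frameshift
    counts, the fraction of InDels hitting CDS, and percentage-of-genome
    figures for repeats / genes / CDS.
    """
    total_len = assembly.total_length
    exon_len = merged_length(annotation.exons) if len(annotation.exons) else 0
    gene_len = merged_length(annotation.genes) if len(annotation.genes) else 0
    intron_len = max(gene_len - exon_len, 0)
    intergenic_len = max(total_len - gene_len, 0)
    lengths = {"exon": exon_len, "intron": intron_len, "intergenic": intergenic_len}

    snps = classified[classified.vtype == "SNP"]
    indels = classified[classified.vtype == "INDEL"]
    compartments = {}
    for comp in ("exon", "intron", "intergenic"):
        n = int((snps.compartment == comp).sum())
        L = lengths[comp]
        compartments[comp] = {
            "snp_count": n,
            "length": L,
            "snp_rate_percent": (100.0 * n / L) if L else None,
        }
        if L == 0 and n:
            compartments[comp]["flag"] = "zero-length compartment with variants"

    n_syn = int((snps.coding_effect == "synonymous").sum())
    n_nonsyn = int((snps.coding_effect.isin(["nonsynonymous", "stop_gained"])).sum())
    syn_nonsyn = (n_syn / n_nonsyn) if n_nonsyn else (float("inf") if n_syn else None)
    n_frameshift = int((indels.coding_effect == "frameshift").sum())
    n_cds_indel = int((indels.coding_effect.isin(["frameshift", "inframe"])).sum())
    cds_indel_percent = (round(100.0 * n_cds_indel / len(indels), 2)
                         if len(indels) else None)

    repeat_len = merged_length(annotation.tes) if len(annotation.tes) else 0
    cds_len = merged_length(annotation.cds) if len(annotation.cds) else 0
    return {
        "compartments": compartments,
        "ts_tv": ts_tv(snps) if len(snps) else None,
        "syn_nonsyn_ratio": syn_nonsyn,
        "frameshift_indels": n_frameshift,
        "cds_indels": n_cds_indel,
        "cds_indel_percent": cds_indel_percent,
        "genome_percent": {
            "repeats": percent_of_genome(repeat_len, total_len),
            "genes": percent_of_genome(gene_len, total_len),
            "cds": percent_of_genome(cds_len, total_len),
        },
    }
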