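"""Synthetic diploid-genome bundles with known ground truth.

The generator emulates the data structure of a highly inbred diploid
genome: a two-state (purged/retained) heterozygosity landscape, gene
models with intact open reading frames, transposable-element insertion
bursts at chosen divergences, and integrated retroviral proviruses.
Every emitted annotation is mirrored in a ground-truth table so each
downstream analysis stage can be scored against what was planted.

Randomness is split into one independent stream per output class
(genome, genes, TEs, proviruses, variants), so e.g. adding a TE burst
does not perturb variant placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Assembly, AnnotationSet, VariantSet, revcomp, write_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS
)
# transition partner for each base; transversion alternatives are the rest
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

MAX_HET_RATE = 0.05

# default gammaretrovirus-like component lengths (bp)
PROVIRUS_COMPONENT_LENGTHS = {"LTR": 600, "gag": 1500, "pol": 3600, "env": 2000}
PROVIRUS_ORDER = ("LTR", "gag", "pol", "env", "LTR")


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_from_consensus(consensus: str, divergence: float, seed=None) -> str:
    """Mutate a consensus by independent per-site substitution.

    Each position is substituted with probability ``divergence``, choosing
    uniformly among the three alternative bases.  This is the inverse of
    the copy-vs-consensus divergence measurement: a copy simulated at
    divergence *d* shows a mismatch fraction binomially distributed
    around *d*.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _str_to_codes(consensus)
    mask = rng.random(codes.size) < divergence
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return _codes_to_str(codes)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic inbred-diploid bundle.

    Default rates mirror a genome where the combined heterozygosity is
    ~0.135% overall but ~60% of windows are nearly devoid of
    heterozygosity: alternating retained blocks at ``het_rate_retained``
    and purged blocks at ``het_rate_purged``, block lengths geometric
    with mean ``mean_block_length``.
    """

    genome_length: int = 2_000_000
    window_purged_fraction: float = 0.6
    het_rate_retained: float = 0.0033
    het_rate_purged: float = 0.00005
    indel_fraction: float = 0.126          # fraction of het sites that are InDels
    ts_fraction: float = 2.54 / 3.54       # P(SNP is a transition)
    te_bursts: list = field(default_factory=lambda: [
        ("SINE_A", 150, 0.10, 0.02),
        ("SINE_B", 150, 0.20, 0.02),
    ])
    provirus_count: int = 2
    fragment_count: int = 6
    gene_count: int | None = None          # default: one gene per 100 kb
    mean_block_length: int = 500_000
    te_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("window_purged_fraction", "het_rate_retained",
                     "het_rate_purged", "indel_fraction", "ts_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("het_rate_retained", "het_rate_purged"):
            if getattr(self, name) > MAX_HET_RATE:
                raise ValueError(
                    f"{name} > {MAX_HET_RATE} is unrealistically dense and breaks "
                    "window statistics; choose a per-base rate at or below "
                    f"{MAX_HET_RATE}")

    @property
    def n_genes(self) -> int:
        return self.gene_count if self.gene_count is not None else self.genome_length // 100_000


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream calls.

    All coordinates 0-based half-open on the emitted assembly.
    """

    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    state_blocks: pd.DataFrame = field(default_factory=pd.DataFrame)
    te_copies: pd.DataFrame = field(default_factory=pd.DataFrame)
    proviruses: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for name in ("variants", "state_blocks", "te_copies", "proviruses"):
            df = getattr(self, name)
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


@dataclass
class SimulatedBundle:
    assembly: Assembly
    annotation: AnnotationSet
    variants: VariantSet
    truth: GroundTruth
    consensus_library: dict[str, str]
    provirus_library: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/GFF3/VCF/BED plus tab-separated truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.assembly.to_fasta(outdir / "assembly.fasta")
        self.annotation.to_gff3(outdir / "genes.gff3")
        self.variants.to_vcf(outdir / "variants.vcf", self.assembly)
        if len(self.annotation.tes):
            write_bed(self.annotation.tes, outdir / "te_copies.bed", extra=["copy_id", "family"])
            with open(outdir / "te_copies.fasta", "w") as fh:
                for t in self.annotation.tes.itertuples(index=False):
                    fh.write(f">{t.copy_id}\n{self.assembly.fetch(t.chrom, t.start, t.end)}\n")
        with open(outdir / "consensus_library.fasta", "w") as fh:
            for name, seq in self.consensus_library.items():
                fh.write(f">{name}\n{seq}\n")
        with open(outdir / "provirus_queries.fasta", "w") as fh:
            for name, seq in self.provirus_library.items():
                fh.write(f">{name}\n{seq}\n")
        if len(self.truth.state_blocks):
            write_bed(self.truth.state_blocks, outdir / "state_blocks.bed", extra=["state"])
        self.truth.write(outdir)


def _class_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, sum(stream.encode())])


def _geometric_blocks(length: int, purged_fraction: float, mean_block: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Alternating purged/retained blocks; geometric lengths chosen so the
    stationary purged fraction equals ``purged_fraction``."""
    if purged_fraction <= 0.0:
        return pd.DataFrame([("retained", 0, length)], columns=["state", "start", "end"])
    if purged_fraction >= 1.0:
        return pd.DataFrame([("purged", 0, length)], columns=["state", "start", "end"])
    mean_p = max(2.0 * mean_block * purged_fraction, 1.0)
    mean_r = max(2.0 * mean_block * (1.0 - purged_fraction), 1.0)
    state = "purged" if rng.random() < purged_fraction else "retained"
    pos, rows = 0, []
    while pos < length:
        mean = mean_p if state == "purged" else mean_r
        blk = int(min(rng.geometric(1.0 / mean), length - pos))
        rows.append((state, pos, pos + blk))
        pos += blk
        state = "retained" if state == "purged" else "purged"
    return pd.DataFrame(rows, columns=["state", "start", "end"])


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + sense codons + stop: a CDS guaranteed free of in-frame stops."""
    body = rng.choice(len(_SENSE_CODONS), size=max(n_codons - 2, 1))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _place_intervals(n: int, lengths: list[int], genome_length: int,
                     occupied: list[tuple[int, int]], rng: np.random.Generator,
                     max_tries: int = 200) -> list[tuple[int, int]]:
    """Sample n non-overlapping intervals avoiding already-occupied spans."""
    placed = []
    occ = sorted(occupied)

    def collides(s: int, e: int) -> bool:
        import bisect
        i = bisect.bisect_left(occ, (s, s))
        for j in (i - 1, i):
            if 0 <= j < len(occ) and occ[j][0] < e and s < occ[j][1]:
                return True
        return False

    import bisect
    for L in lengths[:n]:
        if genome_length <= L:
            raise ValueError("could not place interval; genome too crowded")
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - L))
            if not collides(s, s + L):
                bisect.insort(occ, (s, s + L))
                placed.append((s, s + L))
                break
        else:
            # rejection sampling failed (crowded genome): fall back to an
            # explicit scan of the free gaps and pick one at random
            gaps, prev = [], 0
            for os_, oe in occ:
                if os_ - prev >= L:
                    gaps.append((prev, os_))
                prev = max(prev, oe)
            if genome_length - prev >= L:
                gaps.append((prev, genome_length))
            if not gaps:
                raise ValueError("could not place interval; genome too crowded")
            gs, ge = gaps[int(rng.integers(0, len(gaps)))]
            s = int(rng.integers(gs, ge - L + 1))
            bisect.insort(occ, (s, s + L))
            placed.append((s, s + L))
    return placed


def _build_genes(codes: np.ndarray, chrom: str, n_genes: int,
                 occupied: list[tuple[int, int]],
                 rng: np.random.Generator) -> tuple[AnnotationSet, list[tuple[int, int]]]:
    genes, exons, cds_rows = [], [], []
    spans = []
    for gi in range(n_genes):
        n_exons = int(rng.integers(2, 6))
        exon_lens = [int(rng.integers(50, 100)) * 3 for _ in range(n_exons)]
        intron_lens = [int(rng.integers(300, 1500)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        placed = _place_intervals(1, [span], codes.size, occupied + spans, rng)
        if not placed:
            continue
        gstart, gend = placed[0]
        spans.append((gstart, gend))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{gi:04d}"
        orf = _random_orf(sum(exon_lens) // 3, rng)
        # lay the ORF across exons in genomic order (reverse-complemented
        # for minus-strand genes so the spliced mRNA reads the ORF)
        genomic_cds = orf if strand == "+" else revcomp(orf)
        exon_coords = []
        pos = gstart
        for k, eL in enumerate(exon_lens):
            exon_coords.append((pos, pos + eL))
            pos += eL + (intron_lens[k] if k < n_exons - 1 else 0)
        off = 0
        for es, ee in exon_coords:
            codes[es:ee] = _str_to_codes(genomic_cds[off:off + (ee - es)])
            off += ee - es
        genes.append((gid, chrom, gstart, exon_coords[-1][1], strand))
        cum = 0
        order = exon_coords if strand == "+" else exon_coords[::-1]
        phases = {}
        for es, ee in order:
            phases[(es, ee)] = (3 - cum % 3) % 3
            cum += ee - es
        for es, ee in exon_coords:
            exons.append((gid, chrom, es, ee))
            cds_rows.append((gid, chrom, es, ee, phases[(es, ee)]))
    ann = AnnotationSet(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
        cds=pd.DataFrame(cds_rows, columns=["gene_id", "chrom", "start", "end", "phase"]),
    )
    return ann, spans


def _plant_tes(codes: np.ndarray, chrom: str, bursts: list, te_length: int,
               occupied: list[tuple[int, int]],
               rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    library: dict[str, str] = {}
    te_rows, truth_rows = [], []
    spans = list(occupied)
    copy_no = 0
    for consensus_id, copy_count, mean_div, sd_div in bursts:
        if consensus_id not in library:
            library[consensus_id] = random_sequence(te_length, rng)
        consensus = library[consensus_id]
        divs = np.clip(rng.normal(mean_div, sd_div, size=copy_count), 0.0, 0.5)
        lengths = [len(consensus)] * copy_count
        placed = _place_intervals(copy_count, lengths, codes.size, spans, rng)
        for (s, e), d in zip(placed, divs):
            copy = mutate_from_consensus(consensus, float(d), rng)
            codes[s:e] = _str_to_codes(copy)
            cid = f"te{copy_no:06d}"
            te_rows.append((cid, chrom, s, e, consensus_id))
            truth_rows.append((cid, chrom, s, e, consensus_id, float(d)))
            spans.append((s, e))
            copy_no += 1
    tes = pd.DataFrame(te_rows, columns=["copy_id", "chrom", "start", "end", "family"])
    truth = pd.DataFrame(truth_rows, columns=["copy_id", "chrom", "start", "end",
                                              "family", "divergence"])
    return tes, truth, library


def make_provirus_library(rng: np.random.Generator,
                          component_lengths: dict[str, int] | None = None) -> dict[str, str]:
    """One reference sequence per provirus component (LTR, gag, pol, env)."""
    lengths = component_lengths or PROVIRUS_COMPONENT_LENGTHS
    return {name: random_sequence(L, rng) for name, L in lengths.items()}


def insert_provirus(assembly: Assembly, component_lengths: dict[str, int] | None = None,
                    count: int = 2, fragment_count: int = 0, seed=0,
                    library: dict[str, str] | None = None,
                    full_divergence: float = 0.02, fragment_divergence: float = 0.15,
                    occupied: list[tuple[int, int]] | None = None,
                    ) -> tuple[Assembly, GroundTruth, dict[str, str]]:
    """Plant full and fragmentary provirus integrations into an assembly.

    Full integrations are collinear LTR-gag-pol-env-LTR on one strand at
    low divergence from the reference virus; fragments are single,
    truncated components at elevated divergence (emulating ancient,
    decayed insertions).  Planting substitutes the host sequence in
    place, so scaffold lengths and existing annotation coordinates are
    preserved.  Returns the modified assembly, the truth table of what
    was planted, and the component library used as the query set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = component_lengths or PROVIRUS_COMPONENT_LENGTHS
    if library is None:
        library = make_provirus_library(rng, lengths)
    total = sum(lengths[c] for c in PROVIRUS_ORDER)
    name = max(assembly.names, key=assembly.length)
    seq_codes = _str_to_codes(assembly[name])
    if count > 0 and assembly.length(name) < total:
        raise ValueError(
            f"scaffold {name} ({assembly.length(name)} bp) too short for a "
            f"{total} bp provirus")
    rows = []
    spans = list(occupied or [])
    if count:
        for k, (s, e) in enumerate(_place_intervals(count, [total] * count,
                                                    seq_codes.size, spans, rng)):
            strand = "+" if rng.random() < 0.5 else "-"
            order = PROVIRUS_ORDER if strand == "+" else PROVIRUS_ORDER[::-1]
            pos = s
            for comp in order:
                mutated = mutate_from_consensus(library[comp], full_divergence, rng)
                if strand == "-":
                    mutated = revcomp(mutated)
                seq_codes[pos:pos + lengths[comp]] = _str_to_codes(mutated)
                rows.append((f"pv{k:03d}", name, pos, pos + lengths[comp], comp,
                             strand, "full"))
                pos += lengths[comp]
            spans.append((s, e))
    for k in range(fragment_count):
        comp = ("gag", "pol", "env", "LTR")[int(rng.integers(0, 4))]
        frac = rng.uniform(0.4, 0.9)
        frag = library[comp][: max(int(lengths[comp] * frac), 30)]
        frag = mutate_from_consensus(frag, fragment_divergence, rng)
        (s, e), = _place_intervals(1, [len(frag)], seq_codes.size, spans, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        seq_codes[s:e] = _str_to_codes(frag if strand == "+" else revcomp(frag))
        rows.append((f"frag{k:03d}", name, s, e, comp, strand, "fragment"))
        spans.append((s, e))
    truth = GroundTruth(proviruses=pd.DataFrame(
        rows, columns=["insert_id", "chrom", "start", "end", "component",
                       "strand", "completeness"]))
    new_sequences = dict(assembly.sequences)
    new_sequences[name] = _codes_to_str(seq_codes)
    return Assembly(new_sequences), truth, library


def _place_variants(codes: np.ndarray, chrom: str, blocks: pd.DataFrame,
                    cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Heterozygous sites by per-base Bernoulli draws at the block-state rate."""
    rate = np.full(codes.size, cfg.het_rate_retained)
    for b in blocks.itertuples(index=False):
        if b.state == "purged":
            rate[b.start:b.end] = cfg.het_rate_purged
    positions = np.nonzero(rng.random(codes.size) < rate)[0]
    if positions.size == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "vtype"])
    is_indel = rng.random(positions.size) < cfg.indel_fraction
    rows = []
    blocked_until = -1
    seq = _codes_to_str(codes)
    for pos, indel in zip(positions.tolist(), is_indel.tolist()):
        if pos <= blocked_until:
            continue  # drop variants swallowed by a previous deletion
        ref_base = seq[pos]
        if not indel:
            if rng.random() < cfg.ts_fraction:
                alt = _TRANSITION[ref_base]
            else:
                choices = [b for b in "ACGT" if b != ref_base and b != _TRANSITION[ref_base]]
                alt = choices[int(rng.integers(0, 2))]
            rows.append((chrom, pos, ref_base, alt, "SNP"))
            blocked_until = pos
        else:
            length = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion: REF spans anchor + deleted bases
                if pos + 1 + length > codes.size:
                    continue
                rows.append((chrom, pos, seq[pos:pos + 1 + length], ref_base, "INDEL"))
                blocked_until = pos + length
            else:  # insertion after the anchor base
                ins = random_sequence(length, rng)
                rows.append((chrom, pos, ref_base, ref_base + ins, "INDEL"))
                blocked_until = pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])


def simulate_genome(config: SimulationConfig) -> SimulatedBundle:
    """Generate a full synthetic bundle: assembly, annotation, variants, truth.

    Stages run in a fixed order on the reference sequence (genes, TE
    bursts, proviruses, then variants), each from its own random stream
    seeded from ``config.seed``.  Variant REF alleles are read from the
    final reference, so the emitted VCF round-trips against the FASTA.
    """
    chrom = "scaffold_1"
    genome_rng = _class_rng(config.seed, "genome")
    gene_rng = _class_rng(config.seed, "genes")
    te_rng = _class_rng(config.seed, "tes")
    pv_rng = _class_rng(config.seed, "proviruses")
    var_rng = _class_rng(config.seed, "variants")

    codes = genome_rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    blocks = _geometric_blocks(config.genome_length, config.window_purged_fraction,
                               config.mean_block_length, genome_rng)
    blocks.insert(0, "chrom", chrom)
    blocks = blocks[["chrom", "start", "end", "state"]]

    ann, gene_spans = _build_genes(codes, chrom, config.n_genes, [], gene_rng)
    tes, te_truth, library = _plant_tes(codes, chrom, config.te_bursts,
                                        config.te_length, gene_spans, te_rng)
    ann.tes = tes

    occupied = gene_spans + [(t.start, t.end) for t in tes.itertuples(index=False)]
    assembly = Assembly({chrom: _codes_to_str(codes)})
    pv_library: dict[str, str] = {}
    pv_truth = pd.DataFrame(columns=["insert_id", "chrom", "start", "end",
                                     "component", "strand", "completeness"])
    if config.provirus_count or config.fragment_count:
        assembly, pv_gt, pv_library = insert_provirus(
            assembly, count=config.provirus_count,
            fragment_count=config.fragment_count, seed=pv_rng,
            occupied=occupied)
        pv_truth = pv_gt.proviruses
        codes = _str_to_codes(assembly[chrom])

    var_df = _place_variants(codes, chrom, blocks, config, var_rng)
    truth = GroundTruth(variants=var_df.copy(), state_blocks=blocks,
                        te_copies=te_truth, proviruses=pv_truth)
    return SimulatedBundle(assembly=assembly, annotation=ann,
                           variants=VariantSet(var_df), truth=truth,
                           consensus_library=library, provirus_library=pv_library)


def simulate_reads(assembly: Assembly, coverage: float = 30.0, read_length: int = 100,
                   error_rate: float = 0.0, seed=0) -> list[str]:
    """Uniformly sampled single-end reads with independent per-base errors.

    Returns plain sequence strings (sufficient for k-mer work); no
    quality model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[str] = []
    for name in assembly.names:
        codes = _str_to_codes(assembly[name])
        L = codes.size
        if L < read_length:
            continue
        n_reads = int(round(coverage * L / read_length))
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
        mat = codes[starts[:, None] + np.arange(read_length)[None, :]]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            n = int(err.sum())
            if n:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
        flat = _BASES[mat].tobytes().decode()
        reads.extend(flat[i * read_length:(i + 1) * read_length] for i in range(n_reads))
    if not reads:
        raise ValueError("assembly shorter than read length; no reads simulated")
    return reads


def simulate_read_pairs(assembly: Assembly, region: tuple[str, int, int],
                        n_pairs: int = 50, read_length: int = 100,
                        insert_mean: float = 500.0, insert_sd: float = 50.0,
                        seed=0) -> pd.DataFrame:
    """Proper FR read pairs whose inserts are centred on a genomic region.

    Used to exercise junction-support counting: pairs are drawn so that
    inserts straddle the region boundaries as real libraries would.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom, start, end = region
    L = assembly.length(chrom)
    rows = []
    for i in range(n_pairs):
        insert = max(int(rng.normal(insert_mean, insert_sd)), 2 * read_length + 10)
        anchor = int(rng.integers(start - insert, end + insert))
        s1 = max(anchor, 0)
        s2 = min(s1 + insert - read_length, L - read_length)
        rows.append((f"pair{i:05d}", chrom, s1, s1 + read_length, "+",
                     chrom, s2, s2 + read_length, "-"))
    return pd.DataFrame(rows, columns=["name", "chrom1", "start1", "end1", "strand1",
                                       "chrom2", "start2", "end2", "strand2"])
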