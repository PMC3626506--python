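"""Windowed heterozygosity, purging statistics and pedigree expectations.

The central object is a profile of fixed-width, non-overlapping windows
tiled along each scaffold, each carrying the count of heterozygous sites
and the resulting per-base rate.  In a deeply inbred diploid this
profile is bimodal: most windows sit near zero ("purged" by inbreeding)
while a minority retain outbred-level heterozygosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Assembly, AnnotationSet, VariantSet


@dataclass
class WindowProfile:
    """Non-overlapping windows with per-window heterozygosity.

    ``windows`` columns: chrom, start, end, callable_bases, het_sites,
    het_rate (= het_sites / callable_bases).  Coordinates 0-based
    half-open; tail windows shorter than half the window width are
    dropped to avoid rate inflation from tiny denominators.
    """

    windows: pd.DataFrame
    width: int

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class HetSummary:
    snp_count: int
    indel_count: int
    snp_rate: float
    indel_rate: float

    @property
    def combined_rate(self) -> float:
        return self.snp_rate + self.indel_rate


def window_heterozygosity(variants: VariantSet, assembly: Assembly,
                          width: int = 50_000) -> WindowProfile:
    """Tile each scaffold with ``width``-bp windows and count het sites.

    SNPs and InDels each count as one heterozygous site at their anchor
    position.  A variant beyond the scaffold end indicates inconsistent
    inputs and raises.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    for chrom, grp in variants.df.groupby("chrom"):
        if chrom not in assembly:
            raise ValueError(f"variant scaffold {chrom!r} absent from assembly")
        if int(grp.pos.max()) >= assembly.length(chrom):
            raise ValueError(f"variant position beyond end of {chrom}")
    rows = []
    for chrom in assembly.names:
        L = assembly.length(chrom)
        seq = assembly[chrom]
        n_full = L // width
        n_windows = n_full + (1 if L % width >= width / 2 else 0)
        if n_windows == 0:
            continue
        sub = variants.df[variants.df.chrom == chrom]
        pos = sub.pos.to_numpy()
        edges = [i * width for i in range(n_windows)] + [min(n_windows * width, L)]
        counts, _ = np.histogram(pos, bins=edges) if len(pos) else (np.zeros(n_windows, int), None)
        for i in range(n_windows):
            s, e = edges[i], edges[i + 1]
            callable_b = (e - s) - seq.count("N", s, e)
            rate = counts[i] / callable_b if callable_b else 0.0
            rows.append((chrom, s, e, callable_b, int(counts[i]), rate))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "callable_bases",
                                     "het_sites", "het_rate"])
    return WindowProfile(windows=df, width=width)


def genome_rates(variants: VariantSet, callable_bases: int) -> HetSummary:
    """Genome-wide SNP, InDel and combined heterozygosity rates.

    ``callable_bases`` is the denominator (non-gap assembly positions by
    default elsewhere); both rates share it, so the combined rate is
    their sum.
    """
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    n_snp = int((variants.df.vtype == "SNP").sum())
    n_indel = int((variants.df.vtype == "INDEL").sum())
    return HetSummary(snp_count=n_snp, indel_count=n_indel,
                      snp_rate=n_snp / callable_bases,
                      indel_rate=n_indel / callable_bases)


def fraction_below(profile: WindowProfile, threshold: float) -> float:
    """Percentage of windows with het_rate strictly below ``threshold``."""
    if len(profile) == 0:
        raise ValueError("empty window profile")
    frac = (profile.windows.het_rate < threshold).mean()
    return 100.0 * float(frac)


def top_divergent_regions(profile: WindowProfile, top_fraction: float = 0.05) -> pd.DataFrame:
    """The most heterozygous ``top_fraction`` of windows, merged when adjacent.

    Windows are ranked by het_rate (ties broken by genomic coordinate so
    the selection is deterministic); the top ceil(N * fraction) windows
    are kept and runs of adjacent selected windows are merged into
    regions.  Returns region rows with the min and max rate inside each.
    """
    if len(profile) == 0:
        raise ValueError("empty window profile")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    w = profile.windows.reset_index(drop=True)
    n_top = max(int(np.ceil(len(w) * top_fraction)), 1)
    order = w.sort_values(["het_rate", "chrom", "start"],
                          ascending=[False, True, True], kind="stable")
    sel = order.head(n_top).sort_values(["chrom", "start"])
    regions = []
    cur = None
    for row in sel.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start == cur["end"]:
            cur["end"] = row.end
            cur["min_rate"] = min(cur["min_rate"], row.het_rate)
            cur["max_rate"] = max(cur["max_rate"], row.het_rate)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "min_rate": row.het_rate, "max_rate": row.het_rate, "n_windows": 1}
    if cur is not None:
        regions.append(cur)
    return pd.DataFrame(regions, columns=["chrom", "start", "end",
                                          "min_rate", "max_rate", "n_windows"])


def gene_heterozygosity(variants: VariantSet, annotation: AnnotationSet) -> pd.DataFrame:
    """Per-gene heterozygosity over the genomic gene span.

    A variant inside overlapping genes is assigned to every overlapping
    gene.  Returns one row per gene with het_sites, span and het_rate,
    sorted most-heterozygous first.
    """
    rows = []
    by_chrom = {c: np.sort(g.pos.to_numpy()) for c, g in variants.df.groupby("chrom")}
    for g in annotation.genes.itertuples(index=False):
        pos = by_chrom.get(g.chrom, np.empty(0, dtype=np.int64))
        n = int(np.searchsorted(pos, g.end, "left") - np.searchsorted(pos, g.start, "left"))
        span = g.end - g.start
        rows.append((g.gene_id, g.chrom, g.start, g.end, n, span,
                     n / span if span else 0.0))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "het_sites", "span", "het_rate"])
    return df.sort_values(["het_rate", "gene_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def top_heterozygous_genes(table: pd.DataFrame, n: int = 1000,
                           min_rate: float = 0.0) -> pd.DataFrame:
    """Top-N most heterozygous genes subject to a rate floor."""
    return table[table.het_rate >= min_rate].head(n).reset_index(drop=True)


def inbreeding_coefficient(generations: int) -> float:
    """Inbreeding coefficient after t generations of full-sib mating.

    Follows the classical recurrence F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4
    with F_0 = F_{-1} = 0, i.e. F_1 = 0.25 for the first full-sib
    offspring, approaching 1 geometrically.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(generations):
        f_prev2, f_prev1 = f_prev1, (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
    return f_prev1


def expected_heterozygosity(h0: float, generations: int) -> float:
    """Expected heterozygosity H_t = H_0 (1 - F_t) under full-sib inbreeding."""
    return h0 * (1.0 - inbreeding_coefficient(generations))


def expected_vs_observed(expected, observed) -> float:
    """Pearson correlation between pedigree-expected and observed
    per-individual heterozygosity.

    Returns NaN (with a warning) when either vector has zero variance;
    requires at least 3 paired values.
    """
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if expected.shape != observed.shape:
        raise ValueError("expected and observed must have equal length")
    if expected.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(expected) == 0.0 or np.std(observed) == 0.0:
        warnings.warn("zero variance in one vector; correlation undefined")
        return float("nan")
    r, _ = stats.pearsonr(expected, observed)
    return float(r)
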