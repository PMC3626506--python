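"""Transposable-element clustering, consensus inference and divergence dating.

Copies are clustered by greedy centroid assignment (longest first, each
copy joining the first group whose centroid it matches at or above a
global-identity threshold), a consensus is called per group by
column-majority over a star alignment, and each copy's divergence from
its consensus — the mismatch proportion over aligned non-gap columns —
serves as a molecular clock proxy: a burst of transposition appears as
a mode in the divergence distribution, and dividing the mode by a
neutral substitution rate dates the burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .annotate import merged_length
from .io import Assembly, AnnotationSet

# Affine-gap global aligner for divergence measurement.  Unit-cost edit
# distance is unusable here: it happily trades a run of mismatches for an
# insertion/deletion pair, and with gap columns excluded from the metric
# that systematically deflates divergence on substitution-rich copies.
# Affine penalties keep substitution-only alignments gapless.
_DIV_ALIGNER = None


def _divergence_aligner():
    global _DIV_ALIGNER
    if _DIV_ALIGNER is None:
        from Bio import Align

        _DIV_ALIGNER = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-2,
            open_gap_score=-6, extend_gap_score=-1)
    return _DIV_ALIGNER


def _align_stats(query: str, target: str) -> tuple[int, int, int]:
    """Affine-gap global alignment -> (matches, mismatches, gap columns)."""
    counts = _divergence_aligner().align(query, target)[0].counts()
    return int(counts.identities), int(counts.mismatches), int(counts.gaps)


def global_identity(a: str, b: str) -> float:
    """Matches over all alignment columns (gaps count against identity)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    m, x, g = _align_stats(a, b)
    return m / (m + x + g)


def copy_divergence(copy: str, consensus: str) -> float:
    """Mismatch proportion between a copy and its consensus.

    Computed over aligned non-gap columns of a global pairwise
    alignment; gap columns are excluded from numerator and denominator,
    so InDel accumulation does not inflate the substitution clock.
    Symmetric in its arguments.
    """
    if not copy or not consensus:
        raise ValueError("cannot align empty sequences")
    m, x, _ = _align_stats(copy, consensus)
    if m + x == 0:
        raise ValueError("alignment has no aligned columns")
    return x / (m + x)


def kimura_divergence(copy: str, consensus: str) -> float:
    """Optional Jukes-Cantor-style corrected divergence (off by default in
    summaries): d = -3/4 ln(1 - 4p/3) on the raw mismatch proportion."""
    p = copy_divergence(copy, consensus)
    if p >= 0.75:
        return float("inf")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def gap_fraction(copy: str, consensus: str) -> float:
    m, x, g = _align_stats(copy, consensus)
    return g / (m + x + g)


@dataclass
class TEGroup:
    group_id: str
    members: dict[str, str]                  # copy_id -> sequence
    consensus: str = ""
    divergences: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def cluster_copies(copies: dict[str, str], identity_threshold: float = 0.8) -> list[TEGroup]:
    """Greedy centroid clustering of TE copies.

    Copies are processed longest-first (ties by id, so the outcome is
    deterministic); each joins the first existing group whose centroid
    aligns at >= ``identity_threshold`` global identity, otherwise it
    founds a new group with itself as centroid.  Equivalent to all-pairs
    single-centroid clustering when families are well separated.
    """
    if not copies:
        raise ValueError("no copies to cluster")
    order = sorted(copies, key=lambda cid: (-len(copies[cid]), cid))
    groups: list[TEGroup] = []
    centroids: list[str] = []
    for cid in order:
        seq = copies[cid]
        for g, centroid in zip(groups, centroids):
            if global_identity(seq, centroid) >= identity_threshold:
                g.members[cid] = seq
                break
        else:
            groups.append(TEGroup(group_id=f"group{len(groups):03d}", members={cid: seq}))
            centroids.append(seq)
    return groups


def refine_groups(groups: list[TEGroup], identity_threshold: float = 0.8) -> list[TEGroup]:
    """One refinement pass over a greedy clustering.

    Greedy centroid clustering anchors each group on a member copy, so a
    diverged family can shatter when copy-to-copy identity straddles the
    threshold even though every copy matches the family consensus
    comfortably.  This pass (1) merges groups whose consensuses align at
    or above the threshold and (2) reassigns every copy to the
    highest-identity consensus, founding a new group only when no
    consensus qualifies.
    """
    consensuses = [build_consensus(g) for g in groups]
    order = sorted(range(len(groups)), key=lambda i: (-len(groups[i]), groups[i].group_id))
    kept: list[list[str]] = []        # member-id lists
    kept_cons: list[str] = []
    all_members: dict[str, str] = {}
    for g in groups:
        all_members.update(g.members)
    for i in order:
        for j, cons in enumerate(kept_cons):
            if global_identity(consensuses[i], cons) >= identity_threshold:
                kept[j].extend(groups[i].members)
                break
        else:
            kept.append(list(groups[i].members))
            kept_cons.append(consensuses[i])
    kept_cons = [build_consensus(TEGroup("tmp", {m: all_members[m] for m in ms}))
                 for ms in kept]
    assignments: list[dict[str, str]] = [{} for _ in kept]
    extra: list[TEGroup] = []
    for cid in sorted(all_members):
        seq = all_members[cid]
        scores = [global_identity(seq, cons) for cons in kept_cons]
        best = int(np.argmax(scores))
        if scores[best] >= identity_threshold:
            assignments[best][cid] = seq
        else:
            extra.append(TEGroup("tmp", {cid: seq}))
    out = [TEGroup(group_id=f"group{k:03d}", members=m)
           for k, m in enumerate(assignments) if m]
    for g in extra:
        g.group_id = f"group{len(out):03d}"
        out.append(g)
    return out


def build_consensus(group: TEGroup) -> str:
    """Column-majority consensus of a group.

    Members are star-aligned against the longest member; each alignment
    column takes its majority character (ties to the reference base) and
    columns that are gaps in more than half the members are dropped.  A
    single-member group returns that member unchanged.
    """
    if len(group) == 0:
        raise ValueError("empty group")
    seqs = list(group.members.values())
    if len(seqs) == 1:
        return seqs[0]
    ref = max(seqs, key=len)
    # star alignment: profile per reference column + per-member gap tally
    n_col = len(ref)
    counts = np.zeros((n_col, 5), dtype=np.int64)  # A C G T gap
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    aligner = _divergence_aligner()
    for seq in seqs:
        aln = aligner.align(ref, seq)[0]
        covered = np.zeros(n_col, dtype=bool)
        ref_blocks, seq_blocks = aln.aligned
        for (ts, te_), (qs, _qe) in zip(ref_blocks, seq_blocks):
            covered[ts:te_] = True
            for j in range(te_ - ts):
                counts[ts + j, base_idx.get(seq[qs + j], 0)] += 1
        counts[~covered, 4] += 1  # ref columns this member does not reach
    out = []
    n_members = len(seqs)
    for i in range(n_col):
        if counts[i, 4] * 2 > n_members:
            continue  # gap-majority column dropped
        best = int(np.argmax(counts[i, :4]))
        # tie-break toward the reference base for determinism
        ref_b = base_idx.get(ref[i], 0)
        if counts[i, ref_b] == counts[i, best]:
            best = ref_b
        out.append("ACGT"[best])
    return "".join(out)


def assign_divergences(groups: list[TEGroup], corrected: bool = False) -> list[TEGroup]:
    """Infer each group's consensus and score every member against it."""
    metric = kimura_divergence if corrected else copy_divergence
    for g in groups:
        g.consensus = build_consensus(g)
        g.divergences = {cid: metric(seq, g.consensus) for cid, seq in g.members.items()}
    return groups


@dataclass
class DivergenceProfile:
    bin_edges: np.ndarray
    densities: np.ndarray
    peaks: list[float]


def detect_peaks(divergences, bandwidth: float | None = None,
                 prominence_fraction: float = 0.05,
                 grid_points: int = 512) -> list[float]:
    """Modes of the copy-divergence distribution via kernel density.

    A Gaussian KDE (Scott bandwidth unless ``bandwidth`` is given, in
    units of divergence) is evaluated on a regular grid and local maxima
    with prominence above ``prominence_fraction`` of the global maximum
    are reported, sorted by location.  Needs >= 50 values for a stable
    density; a degenerate all-equal sample returns its single value.
    """
    values = np.asarray(list(divergences), dtype=float)
    if values.size < 50:
        raise ValueError(f"need >= 50 divergence values for a stable density, got {values.size}")
    if np.ptp(values) == 0.0:
        return [float(values[0])]
    kde = stats.gaussian_kde(values)
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / values.std(ddof=1))
    pad = 3.0 * values.std(ddof=1)
    grid = np.linspace(max(values.min() - pad, 0.0), values.max() + pad, grid_points)
    dens = kde(grid)
    idx, _ = signal.find_peaks(dens, prominence=prominence_fraction * dens.max())
    if idx.size == 0:
        idx = np.array([int(np.argmax(dens))])
    return sorted(float(grid[i]) for i in idx)


def divergence_profile(divergences, n_bins: int = 50, **peak_kwargs) -> DivergenceProfile:
    values = np.asarray(list(divergences), dtype=float)
    dens, edges = np.histogram(values, bins=n_bins, density=True)
    return DivergenceProfile(bin_edges=edges, densities=dens,
                             peaks=detect_peaks(values, **peak_kwargs))


def date_expansion(peak: float, rate: float) -> float:
    """Age of an expansion burst in Myr: divergence peak / substitution rate.

    ``rate`` is in substitutions per site per Myr; copies diverge from
    the master/consensus lineage after insertion, so the peak divergence
    reads directly as elapsed time times rate.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if peak < 0:
        raise ValueError("divergence peak must be non-negative")
    return peak / rate


def constrain_interval(origin_min: float, speciation: float) -> tuple[float, float]:
    """Bracket an expansion between its minimum age and a speciation bound.

    A family absent from a sister lineage must have expanded after the
    split, so (minimum origin, speciation time) brackets the burst.
    """
    if origin_min > speciation:
        raise ValueError(f"origin_min {origin_min} exceeds speciation bound {speciation}")
    return (origin_min, speciation)


def repeat_summary(annotation: AnnotationSet, assembly: Assembly,
                   length_range: tuple[int, int] = (100, 300)) -> dict:
    """Per-family genome occupancy and copy-length distribution.

    Reports, per repeat family and overall: copy count, total bases,
    percentage of the assembly, plus a length histogram with its modal
    lengths and the fraction of copies inside ``length_range``.
    """
    total = assembly.total_length
    tes = annotation.tes
    out: dict = {"families": {}, "total": {}}
    if len(tes) == 0:
        out["total"] = {"copies": 0, "bases": 0, "percent_of_genome": 0.0,
                        "fraction_in_range": 0.0, "length_modes": []}
        return out
    lengths = (tes.end - tes.start).to_numpy()
    for fam, grp in tes.groupby("family"):
        bases = merged_length(grp[["chrom", "start", "end"]])
        out["families"][fam] = {
            "copies": int(len(grp)),
            "bases": int(bases),
            "percent_of_genome": round(100.0 * bases / total, 1),
        }
    all_bases = merged_length(tes[["chrom", "start", "end"]])
    counts, edges = np.histogram(lengths, bins=min(50, max(int(lengths.max()) // 10, 1)))
    modes_idx, _ = signal.find_peaks(counts, prominence=0.05 * counts.max())
    if modes_idx.size == 0:
        modes_idx = np.array([int(np.argmax(counts))])
    modes = [float((edges[i] + edges[i + 1]) / 2) for i in modes_idx]
    lo, hi = length_range
    out["total"] = {
        "copies": int(len(tes)),
        "bases": int(all_bases),
        "percent_of_genome": round(100.0 * all_bases / total, 1),
        "fraction_in_range": float(((lengths >= lo) & (lengths <= hi)).mean()),
        "length_modes": modes,
    }
    return out
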