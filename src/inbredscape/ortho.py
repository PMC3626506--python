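"""Reciprocal-best-hit orthology, gene presence/absence and pseudogene calls.

Orthologs between two proteomes are called by the reciprocal-best-hit
criterion on directed score tables: (a, b) is a pair iff b is a's
unique top score in the a->b direction and a is b's unique top score in
the b->a direction.  Score ties at the top yield no call — a missed
ortholog is cheaper than a false one.  Presence/absence against curated
gene lists and disruption (pseudogene) calling sit on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

_SCORE_COLUMNS = ["gene_a", "gene_b", "score"]


def score_table(rows, identity: bool = False) -> pd.DataFrame:
    """Normalise a directed score table (gene_a, gene_b, score[, identity,
    coverage]); the best row is kept per directed pair."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        ncol = len(rows[0]) if rows else 3
        cols = _SCORE_COLUMNS + ["identity", "coverage"][: ncol - 3]
        df = pd.DataFrame(rows, columns=cols)
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    if (df.score < 0).any():
        raise ValueError("scores must be non-negative")
    df = (df.sort_values("score", ascending=False, kind="stable")
            .drop_duplicates(["gene_a", "gene_b"], keep="first")
            .reset_index(drop=True))
    return df


def _unique_best(df: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    """Per gene_a: its unique top-scoring gene_b; genes with tied tops are
    returned separately as no-call."""
    best: dict[str, str] = {}
    tied: set[str] = set()
    for ga, grp in df.groupby("gene_a"):
        top = grp.score.max()
        winners = grp[grp.score == top].gene_b.unique()
        if len(winners) == 1:
            best[ga] = winners[0]
        else:
            tied.add(ga)
    return best, tied


def reciprocal_best_hits(ab: pd.DataFrame, ba: pd.DataFrame) -> pd.DataFrame:
    """Ortholog pairs by reciprocal best hit.

    Returns a frame with gene_a, gene_b and, when present in the inputs,
    the mean identity of the two directions.  Ties for the top score in
    either direction produce no pair; the tied genes are listed in
    ``attrs['ties']``.
    """
    ab = score_table(ab)
    ba = score_table(ba)
    best_ab, ties_a = _unique_best(ab)
    best_ba, ties_b = _unique_best(ba)
    rows = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            rows.append((a, b))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    if "identity" in ab.columns:
        id_ab = ab.set_index(["gene_a", "gene_b"]).identity
        id_ba = ba.set_index(["gene_a", "gene_b"]).identity
        idents = []
        for a, b in rows:
            vals = [v for v in (id_ab.get((a, b)), id_ba.get((b, a))) if v is not None]
            idents.append(float(np.mean(vals)) if vals else np.nan)
        out["identity"] = idents
    out.attrs["ties"] = {"a": sorted(ties_a), "b": sorted(ties_b)}
    return out


def identity_distribution(pairs: pd.DataFrame, n_bins: int = 40) -> dict:
    """Mean and histogram of per-pair ortholog identities."""
    if len(pairs) == 0:
        raise ValueError("no ortholog pairs")
    if "identity" not in pairs.columns:
        raise ValueError("pairs table lacks an identity column")
    v = pairs.identity.to_numpy(dtype=float)
    counts, edges = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    return {"mean_identity": float(v.mean()), "n_pairs": int(len(v)),
            "bin_edges": edges.tolist(), "counts": counts.tolist()}


def presence_absence(reference_ids, pairs_by_species: dict[str, pd.DataFrame],
                     hits_by_species: dict[str, pd.DataFrame] | None = None,
                     identity_floor: float = 0.3,
                     coverage_floor: float = 0.3) -> pd.DataFrame:
    """Presence/absence of reference genes across species.

    A reference gene is 'present' in a species when it has an RBH
    ortholog there; if it lacks an RBH but some hit passes the identity
    and coverage floors it is 'hit_only' (too diverged to call, but not
    lost); otherwise 'absent'.  Only 'absent' counts toward loss:
    apparent losses can be artefacts of high sequence divergence, so a
    weak-hit floor guards the call.  Species-specific losses (absent in
    exactly one species) are in ``attrs['specific_loss']``.
    """
    raw = list(reference_ids)
    ids = list(dict.fromkeys(raw))
    if len(ids) < len(raw):
        warnings.warn("duplicate reference ids collapsed")
    mat = {}
    for sp, pairs in sorted(pairs_by_species.items()):
        present = set(pairs.gene_a)
        weak = set()
        if hits_by_species and sp in hits_by_species:
            h = hits_by_species[sp]
            ok = h[(h.identity >= identity_floor) & (h.coverage >= coverage_floor)]
            weak = set(ok.gene_a)
        col = []
        for g in ids:
            if g in present:
                col.append("present")
            elif g in weak:
                col.append("hit_only")
            else:
                col.append("absent")
        mat[sp] = col
    df = pd.DataFrame(mat, index=ids).sort_index(axis=1)
    absent = df.eq("absent")
    specific = {}
    for sp in df.columns:
        others_ok = ~absent.drop(columns=sp).any(axis=1)
        specific[sp] = sorted(df.index[absent[sp] & others_ok])
    df.attrs["specific_loss"] = specific
    df.attrs["retained_everywhere"] = sorted(df.index[df.eq("present").all(axis=1)])
    return df


@dataclass
class ProteinGenomeAlignment:
    """A protein-to-genome alignment for one candidate gene locus.

    ``genomic_cds``: the aligned genomic nucleotides on the coding
    strand, spliced and in frame after skipping ``frame_offset`` bases;
    ``gaps``: genomic insertion/deletion events within the aligned CDS,
    as (offset_in_cds, length) with positive length = inserted genomic
    bases and negative = deleted relative to the protein query.
    """

    gene_id: str
    genomic_cds: str
    gaps: list[tuple[int, int]] = field(default_factory=list)
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")


@dataclass
class DisruptionCall:
    gene_id: str
    disruption_type: str   # 'premature_stop' | 'frameshift'
    position: int          # codon index for stops, CDS offset for frameshifts


def pseudogene_disruptions(alignments, stop_tail_fraction: float = 0.05) -> list[DisruptionCall]:
    """Disruption calls over protein-to-genome alignments.

    premature_stop: an in-frame stop codon earlier than the final
    ``stop_tail_fraction`` of the aligned protein (the tail exemption
    avoids flagging species differences in natural stop placement).
    frameshift: any genomic gap whose length is not a multiple of 3.
    Clean alignments yield no calls.
    """
    calls: list[DisruptionCall] = []
    for aln in alignments:
        cds = aln.genomic_cds[aln.frame_offset:]
        n_codons = len(cds) // 3
        cutoff = n_codons * (1.0 - stop_tail_fraction)
        for ci in range(n_codons):
            codon = cds[ci * 3: ci * 3 + 3]
            if "-" in codon or len(codon) < 3:
                continue
            if str(Seq(codon).translate()) == "*" and ci < cutoff:
                calls.append(DisruptionCall(aln.gene_id, "premature_stop", ci))
        for off, length in aln.gaps:
            if length % 3 != 0:
                calls.append(DisruptionCall(aln.gene_id, "frameshift", off))
    return calls
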