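"""Endogenous-retrovirus screening and provirus structure detection.

Homology hits of retroviral queries (gag, pol, env, LTR) against the
assembly are scored by the product of query coverage and identity; on
real genomes this score is bimodal, separating ancient decayed
insertions from young, potentially replication-competent ones.  Hits
passing strict identity/coverage thresholds are candidate active
elements, and collinear LTR-gag-pol-env-LTR arrangements within a
provirus-sized span are called as complete integrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .io import Assembly, hit_table, revcomp

GENE_CLASSES = ("gag", "pol", "env")


def score_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Add the coverage x identity score column.

    Both factors live in [0, 1]; values outside that range indicate a
    malformed hit table and raise.
    """
    df = hit_table(hits)
    for col in ("identity", "query_coverage"):
        v = df[col].to_numpy(dtype=float)
        if len(v) and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
            raise ValueError(f"{col} outside [0, 1]; got range "
                             f"[{np.nanmin(v)}, {np.nanmax(v)}]")
    df["score"] = df["identity"] * df["query_coverage"]
    return df


def score_distribution(scored: pd.DataFrame, n_bins: int = 40) -> dict:
    """Summary of the coverage x identity score distribution (for plotting
    and for eyeballing the ancient/active bimodality)."""
    s = scored["score"].to_numpy(dtype=float)
    counts, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
    return {"bin_edges": edges.tolist(), "counts": counts.tolist(),
            "n": int(len(s)), "mean": float(s.mean()) if len(s) else None}


def filter_active(hits: pd.DataFrame, identity_min: float = 0.8,
                  coverage_min: float = 0.8) -> pd.DataFrame:
    """Hits with identity AND coverage strictly above their thresholds.

    Strict inequality: a hit at exactly 80% identity is excluded.  The
    survivors are the candidate still-active elements; per-class counts
    are in ``class_counts`` on the returned frame's attrs.
    """
    df = hit_table(hits)
    out = df[(df.identity > identity_min) & (df.query_coverage > coverage_min)].copy()
    out.attrs["class_counts"] = out.query_class.value_counts().to_dict()
    return out


@dataclass
class ProvirusCall:
    scaffold: str
    start: int
    end: int
    strand: str
    completeness: str                      # 'full' | 'partial'
    components: list[tuple[str, int, int]] = field(default_factory=list)
    junction_support: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def detect_provirus(hits: pd.DataFrame, max_span: int = 12_000) -> list[ProvirusCall]:
    """Call complete proviruses from component hits.

    Per scaffold and strand, LTR hits are scanned left to right; a pair
    of LTRs within ``max_span`` that encloses at least one gag, one pol
    and one env hit, in genomic order consistent with the strand
    (gag < pol < env for '+', reversed for '-'), is assembled into a
    full call.  Each hit participates in at most one full call
    (leftmost-first), and leftover component hits are reported as
    partial calls.
    """
    df = hit_table(hits).reset_index(drop=True)
    df["mid"] = (df.start + df.end) // 2
    used = set()
    calls: list[ProvirusCall] = []
    for (scaf, strand), grp in df.groupby(["scaffold", "strand"]):
        ltrs = grp[grp.query_class == "LTR"].sort_values("start")
        genes = grp[grp.query_class.isin(GENE_CLASSES)]
        ltr_idx = list(ltrs.index)
        for i, li in enumerate(ltr_idx):
            if li in used:
                continue
            left = df.loc[li]
            for lj in ltr_idx[i + 1:]:
                if lj in used:
                    continue
                right = df.loc[lj]
                if right.end - left.start > max_span:
                    break
                inner = genes[(genes.mid > left.end) & (genes.mid < right.start)
                              & (~genes.index.isin(used))]
                picks = {}
                ok = True
                for cls in GENE_CLASSES:
                    cand = inner[inner.query_class == cls]
                    if cand.empty:
                        ok = False
                        break
                    # best-supported hit per class, then leftmost for ties
                    if "score" in cand.columns:
                        cand = cand.sort_values(["score", "start"],
                                                ascending=[False, True], kind="stable")
                    else:
                        cand = cand.sort_values("start")
                    picks[cls] = cand.iloc[0]
                if not ok:
                    continue
                order = [picks[c].mid for c in GENE_CLASSES]
                collinear = (order == sorted(order)) if strand == "+" else \
                            (order == sorted(order, reverse=True))
                if not collinear:
                    continue
                comp = [("LTR", int(left.start), int(left.end))]
                comp += [(c, int(picks[c].start), int(picks[c].end)) for c in GENE_CLASSES]
                comp.append(("LTR", int(right.start), int(right.end)))
                comp.sort(key=lambda t: t[1])
                calls.append(ProvirusCall(scaffold=scaf, start=int(left.start),
                                          end=int(right.end), strand=strand,
                                          completeness="full", components=comp))
                used.update([li, lj] + [int(picks[c].name) for c in GENE_CLASSES])
                break
    for idx, row in df.iterrows():
        if idx in used or row.query_class == "genome":
            continue
        calls.append(ProvirusCall(scaffold=row.scaffold, start=int(row.start),
                                  end=int(row.end), strand=row.strand,
                                  completeness="partial",
                                  components=[(row.query_class, int(row.start), int(row.end))]))
    calls.sort(key=lambda c: (c.scaffold, c.start))
    return calls


def junction_support(call: ProvirusCall, read_pairs: pd.DataFrame,
                     insert_mean: float = 500.0, insert_sd: float = 50.0,
                     n_sd: float = 3.0) -> dict:
    """Count proper read pairs spanning the provirus-host junctions.

    A supporting pair has one mate inside the provirus span and its mate
    in flanking host sequence, in inward (FR) orientation, with implied
    insert size within ``n_sd`` standard deviations of the library mean.
    Pairs with missing mate coordinates are skipped and tallied.

    ``read_pairs`` columns: name, chrom1, start1, end1, strand1, chrom2,
    start2, end2, strand2.
    """
    left_j, right_j = call.start, call.end
    support = {"left": 0, "right": 0, "skipped": 0}
    lo = insert_mean - n_sd * insert_sd
    hi = insert_mean + n_sd * insert_sd
    for rp in read_pairs.itertuples(index=False):
        if any(pd.isna(v) for v in (rp.start1, rp.start2, rp.end1, rp.end2)):
            support["skipped"] += 1
            continue
        if rp.chrom1 != call.scaffold or rp.chrom2 != call.scaffold:
            continue
        a = (int(rp.start1), int(rp.end1), rp.strand1)
        b = (int(rp.start2), int(rp.end2), rp.strand2)
        left_mate, right_mate = (a, b) if a[0] <= b[0] else (b, a)
        if not (left_mate[2] == "+" and right_mate[2] == "-"):
            continue  # not inward-facing
        insert = right_mate[1] - left_mate[0]
        if not lo <= insert <= hi:
            continue
        inside = lambda m: m[0] >= call.start and m[1] <= call.end  # noqa: E731
        for junction, key in ((left_j, "left"), (right_j, "right")):
            if left_mate[1] <= junction <= right_mate[0] and inside(left_mate) != inside(right_mate):
                support[key] += 1
    support["total"] = support["left"] + support["right"]
    return support


_LOCAL_ALIGNER = None


def _local_aligner():
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        from Bio import Align

        _LOCAL_ALIGNER = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-2,
            open_gap_score=-6, extend_gap_score=-1)
    return _LOCAL_ALIGNER


def _local_alignment_stats(query: str, window: str) -> tuple[float, float]:
    """(identity, query_coverage) of an affine local alignment.

    A local alignment self-trims to the homologous core, so a truncated
    fragment reports coverage < 1 and an unrelated window reports a
    short chance segment with negligible coverage — unlike edit-distance
    infix alignment, which stretches the whole query over anything.
    """
    alns = _local_aligner().align(query, window)
    if len(alns) == 0:
        return 0.0, 0.0
    c = alns[0].counts()
    aligned = c.identities + c.mismatches
    if aligned == 0:
        return 0.0, 0.0
    identity = c.identities / (aligned + c.internal_gaps)
    return identity, aligned / len(query)


def search_hits(queries: dict[str, tuple[str, str]], assembly: Assembly,
                min_score: float = 0.2, max_hits_per_query: int = 20) -> pd.DataFrame:
    """Small-scale nucleotide homology search for fixture-sized assemblies.

    ``queries`` maps query_id -> (query_class, sequence).  Each query is
    located (both strands) by iterated best-infix edit-distance
    alignment with masking; each located window is then re-scored with
    an affine local alignment to get honest identity and query
    coverage.  The search stops once the coverage x identity score
    drops below ``min_score``.  Intended for <= 1 Mb fixtures;
    production hit tables come from an external translated search in
    outfmt-6-like form.
    """
    rows = []
    for qid, (qclass, qseq) in queries.items():
        for name in assembly.names:
            target = assembly[name]
            for strand in "+-":
                work = list(target if strand == "+" else revcomp(target))
                L = len(work)
                for _ in range(max_hits_per_query):
                    res = edlib.align(qseq, "".join(work), mode="HW", task="locations")
                    if not res["locations"]:
                        break
                    s, e = res["locations"][0]
                    e += 1
                    pad = max((len(qseq) - (e - s)) + 20, 20)
                    ws, we = max(s - pad, 0), min(e + pad, L)
                    ident, cov = _local_alignment_stats(qseq, "".join(work[ws:we]))
                    if ident * cov < min_score:
                        break
                    if strand == "+":
                        g_start, g_end = s, e
                    else:
                        g_start, g_end = L - e, L - s
                    rows.append((qid, qclass, name, g_start, g_end, strand,
                                 round(ident, 4), round(cov, 4)))
                    work[s:e] = "N" * (e - s)
    df = hit_table(rows) if rows else hit_table([])
    return score_hits(df) if len(df) else df
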