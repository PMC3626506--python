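"""Retroviral hit scoring, active-element filtering, provirus detection."""

import numpy as np
import pandas as pd
import pytest

from inbredscape import erv
from inbredscape.io import Assembly, hit_table
from inbredscape.simulate import random_sequence, simulate_read_pairs


def hit(qid, qclass, start, end, strand="+", identity=0.9, coverage=0.9, scaf="s"):
    return (qid, qclass, scaf, start, end, strand, identity, coverage)


def full_provirus_hits(offset=0, strand="+", scaf="s"):
    comps = [("LTR", 0, 600), ("gag", 600, 2100), ("pol", 2100, 5700),
             ("env", 5700, 7700), ("LTR", 7700, 8300)]
    if strand == "-":
        comps = [(n, 8300 - e, 8300 - s) for n, s, e in comps][::-1]
    return [hit(f"q_{n}", n, offset + s, offset + e, strand) for n, s, e in comps]


class TestScoring:
    def test_score_is_product(self):
        df = erv.score_hits(hit_table([hit("q", "env", 0, 100, identity=1.0, coverage=1.0),
                                       hit("q", "env", 0, 100, identity=0.9, coverage=0.5)]))
        assert list(df.score) == pytest.approx([1.0, 0.45])

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            erv.score_hits(hit_table([hit("q", "env", 0, 100, identity=1.2)]))

    def test_bimodal_mixture_detected_against_bruteforce_density(self, rng):
        # scores drawn from a two-component mixture: the histogram has
        # mass in both an ancient (low-score) and active (high-score) mode
        low = rng.normal(0.35, 0.05, 300).clip(0, 1)
        high = rng.normal(0.9, 0.03, 300).clip(0, 1)
        rows = [hit(f"q{i}", "env", 0, 100, identity=float(np.sqrt(s)),
                    coverage=float(np.sqrt(s))) for i, s in enumerate(np.r_[low, high])]
        scored = erv.score_hits(hit_table(rows))
        dist = erv.score_distribution(scored)
        counts = np.array(dist["counts"])
        centers = (np.array(dist["bin_edges"])[:-1] + np.array(dist["bin_edges"])[1:]) / 2
        lo_mass = counts[(centers > 0.2) & (centers < 0.5)].sum()
        hi_mass = counts[centers > 0.8].sum()
        trough = counts[(centers > 0.55) & (centers < 0.75)].sum()
        assert lo_mass > 5 * max(trough, 1) and hi_mass > 5 * max(trough, 1)


class TestFilterActive:
    def test_boundary_is_strict(self):
        df = hit_table([hit("q", "env", 0, 100, identity=0.8, coverage=0.95),
                        hit("q2", "env", 0, 100, identity=0.95, coverage=0.8),
                        hit("q3", "env", 0, 100, identity=0.81, coverage=0.81)])
        out = erv.filter_active(df)
        assert list(out.query_id) == ["q3"]

    def test_empty_table(self):
        out = erv.filter_active(hit_table([]))
        assert len(out) == 0

    def test_counts_match_truth(self, rng):
        rows, expected = [], {}
        for i in range(200):
            ident, cov = rng.random(), rng.random()
            cls = ("gag", "pol", "env", "LTR")[i % 4]
            rows.append(hit(f"q{i}", cls, 0, 100, identity=ident, coverage=cov))
            if ident > 0.8 and cov > 0.8:
                expected[cls] = expected.get(cls, 0) + 1
        out = erv.filter_active(hit_table(rows))
        assert out.attrs["class_counts"] == expected

    def test_subset_and_idempotent(self, rng):
        rows = [hit(f"q{i}", "env", 0, 100, identity=float(rng.random()),
                    coverage=float(rng.random())) for i in range(50)]
        df = hit_table(rows)
        once = erv.filter_active(df)
        assert set(once.query_id) <= set(df.query_id)
        pd.testing.assert_frame_equal(
            erv.filter_active(once).reset_index(drop=True),
            once.reset_index(drop=True))


class TestDetectProvirus:
    def test_constructed_full_provirus(self):
        calls = erv.detect_provirus(hit_table(full_provirus_hits()))
        full = [c for c in calls if c.completeness == "full"]
        assert len(full) == 1
        assert [c[0] for c in full[0].components] == ["LTR", "gag", "pol", "env", "LTR"]

    def test_lone_env_is_partial(self):
        calls = erv.detect_provirus(hit_table([hit("q", "env", 100, 2100)]))
        assert len(calls) == 1 and calls[0].completeness == "partial"

    def test_ltr_pair_beyond_max_span_not_called(self):
        rows = full_provirus_hits()
        calls = erv.detect_provirus(hit_table(rows), max_span=8_000)
        assert not [c for c in calls if c.completeness == "full"]

    def test_wrong_component_order_not_called(self):
        rows = [hit("q_LTR", "LTR", 0, 600), hit("q_env", "env", 600, 2600),
                hit("q_pol", "pol", 2600, 6200), hit("q_gag", "gag", 6200, 7700),
                hit("q_LTR", "LTR", 7700, 8300)]
        calls = erv.detect_provirus(hit_table(rows))
        assert not [c for c in calls if c.completeness == "full"]

    def test_minus_strand_called(self):
        calls = erv.detect_provirus(hit_table(full_provirus_hits(strand="-")))
        full = [c for c in calls if c.completeness == "full"]
        assert len(full) == 1 and full[0].strand == "-"

    def test_strand_symmetry_under_reverse_complement(self):
        L = 50_000
        rows = full_provirus_hits(offset=10_000, strand="+")
        flipped = [(q, c, s, L - e, L - st, "-" if strand == "+" else "+", i, cv)
                   for q, c, s, st, e, strand, i, cv in rows]
        fwd = [c for c in erv.detect_provirus(hit_table(rows)) if c.completeness == "full"]
        rev = [c for c in erv.detect_provirus(hit_table(flipped)) if c.completeness == "full"]
        assert len(fwd) == len(rev) == 1
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end, L - fwd[0].start)

    def test_full_calls_bounded_by_component_counts(self, rng):
        # random hit tables can never yield more full calls than the
        # limiting component allows
        for trial in range(20):
            n = int(rng.integers(3, 25))
            rows = []
            for i in range(n):
                cls = ("LTR", "gag", "pol", "env")[int(rng.integers(4))]
                s = int(rng.integers(0, 30_000))
                rows.append(hit(f"q{i}", cls, s, s + 500,
                                "+" if rng.random() < 0.5 else "-"))
            df = hit_table(rows)
            calls = erv.detect_provirus(df)
            n_full = sum(c.completeness == "full" for c in calls)
            counts = df.query_class.value_counts()
            bound = min(counts.get("LTR", 0) // 2, counts.get("gag", 0),
                        counts.get("pol", 0), counts.get("env", 0))
            assert n_full <= bound

    def test_generator_truth_recovered(self, bundle):
        # 2 planted full integrations recovered at truth coordinates;
        # fragments never assemble into a false full call
        queries = {f"q_{n}": (n, s) for n, s in bundle.provirus_library.items()}
        hits = erv.search_hits(queries, bundle.assembly)
        calls = erv.detect_provirus(hits)
        full = sorted([c for c in calls if c.completeness == "full"],
                      key=lambda c: c.start)
        truth = (bundle.truth.proviruses.query("completeness == 'full'")
                 .groupby("insert_id").agg(start=("start", "min"), end=("end", "max"))
                 .sort_values("start"))
        assert len(full) == len(truth) == 2
        for call, (_, t) in zip(full, truth.iterrows()):
            assert abs(call.start - t.start) <= 25
            assert abs(call.end - t.end) <= 25


class TestOutfmt6Reader:
    def test_coverage_and_coordinates_converted(self, tmp_path):
        from inbredscape.io import read_hits_outfmt6

        line = "env1\tscaf1\t92.50\t180\t10\t2\t1\t180\t500\t321\t1e-50\t250.0\n"
        (tmp_path / "hits.tsv").write_text(line)
        df = read_hits_outfmt6(tmp_path / "hits.tsv", {"env1": ("env", 200)})
        row = df.iloc[0]
        assert row.query_class == "env"
        assert row.identity == pytest.approx(0.925)
        assert row.query_coverage == pytest.approx(180 / 200)
        assert (row.start, row.end) == (320, 500)  # 0-based half-open
        assert row.strand == "-"


class TestJunctionSupport:
    def make_call(self):
        return erv.ProvirusCall(scaffold="s", start=20_000, end=28_300,
                                strand="+", completeness="full")

    def test_no_pairs_zero(self):
        out = erv.junction_support(self.make_call(), pd.DataFrame(
            columns=["name", "chrom1", "start1", "end1", "strand1",
                     "chrom2", "start2", "end2", "strand2"]))
        assert out["total"] == 0

    def test_constructed_spanning_pairs_counted(self):
        call = self.make_call()
        rows = []
        for i in range(10):
            s1 = call.start - 250 + i  # left mate in host flank
            s2 = call.start + 150 + i  # right mate inside the provirus
            rows.append((f"p{i}", "s", s1, s1 + 100, "+", "s", s2, s2 + 100, "-"))
        pairs = pd.DataFrame(rows, columns=["name", "chrom1", "start1", "end1",
                                            "strand1", "chrom2", "start2", "end2",
                                            "strand2"])
        out = erv.junction_support(call, pairs)
        assert out["left"] == 10 and out["total"] == 10

    def test_missing_mate_coordinates_skipped(self):
        call = self.make_call()
        pairs = pd.DataFrame([("p0", "s", np.nan, np.nan, "+", "s", 20_100, 20_200, "-")],
                             columns=["name", "chrom1", "start1", "end1", "strand1",
                                      "chrom2", "start2", "end2", "strand2"])
        out = erv.junction_support(call, pairs)
        assert out["skipped"] == 1 and out["total"] == 0

    def test_simulated_pairs_match_bruteforce(self, rng):
        asm = Assembly({"s": random_sequence(60_000, rng)})
        call = erv.ProvirusCall(scaffold="s", start=20_000, end=28_300,
                                strand="+", completeness="full")
        pairs = simulate_read_pairs(asm, ("s", 20_000, 28_300), n_pairs=300,
                                    insert_mean=500, insert_sd=50, seed=rng)
        out = erv.junction_support(call, pairs)
        brute = 0
        for rp in pairs.itertuples(index=False):
            a = (rp.start1, rp.end1)
            b = (rp.start2, rp.end2)
            (lm, rm) = (a, b) if a[0] <= b[0] else (b, a)
            if not (350 <= rm[1] - lm[0] <= 650):
                continue
            for j in (20_000, 28_300):
                inside_l = lm[0] >= 20_000 and lm[1] <= 28_300
                inside_r = rm[0] >= 20_000 and rm[1] <= 28_300
                if lm[1] <= j <= rm[0] and inside_l != inside_r:
                    brute += 1
        assert out["total"] == brute
        assert out["total"] > 0
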