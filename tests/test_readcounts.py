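"""Readcount dialect I/O, the trim/cap filter, replicate concordance and
the intersection stages — per-site semantics and the vectorized table
path, which must agree."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolfst.readcounts import (
    ConcordanceResult,
    LibraryTable,
    SiteCounts,
    build_contingency,
    intersect_collections,
    intersect_collections_table,
    intersect_replicates,
    intersect_replicates_table,
    pooled_alt_allele,
    read_readcounts,
    read_readcounts_table,
    replicate_concordance,
    trim_sites,
    trim_table,
    write_readcounts,
)


def sc(pos, counts, contig="c1", ref="A"):
    return SiteCounts(contig, pos, ref, counts)


def _write(tmp_path, text, name="lib.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "contig\tposition\tref\tdepth\tcounts\n"


class TestParsing:
    def test_single_allele_line(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\tA\t30\tA:30\n")
        (site,) = list(read_readcounts(p))
        assert site.total == 30 and site.nid == 1
        assert site.counts == {"A": 30}

    def test_two_alleles_and_alt(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\tA\t30\tA:20\tG:10\n")
        (site,) = list(read_readcounts(p))
        assert site.nid == 2
        assert pooled_alt_allele([site], "A") == "G"

    def test_empty_file_empty_stream(self, tmp_path):
        p = _write(tmp_path, HEADER)
        assert list(read_readcounts(p)) == []

    def test_unknown_token_raises_with_name(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\tA\t30\tQ:30\n")
        with pytest.raises(ValueError, match="'Q'"):
            list(read_readcounts(p))

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\tA\t30\tA:30\nchr1\tXX\tA\t30\tA:30\n")
        with pytest.raises(ValueError, match=":3"):
            list(read_readcounts(p))

    def test_depth_mismatch_warns_sum_wins(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\tA\t99\tA:30\n")
        with pytest.warns(UserWarning, match="using the sum"):
            (site,) = list(read_readcounts(p))
        assert site.total == 30

    def test_roundtrip_reproduces_file(self, tmp_path):
        text = (
            HEADER
            + "chr1\t100\tA\t30\tA:20\tG:10\n"
            + "chr1\t101\tC\t45\tC:40\tT:3\t+AG:2\n"
            + "chr2\t5\tG\t16\tG:16\n"
        )
        p = _write(tmp_path, text)
        out = tmp_path / "out.tsv"
        write_readcounts(read_readcounts(p), out)
        assert out.read_text() == text


class TestTrim:
    def test_boundaries(self):
        sites = [sc(1, {"A": 14}), sc(2, {"A": 15}), sc(3, {"A": 2000}), sc(4, {"A": 2001})]
        kept = [s.position for s in trim_sites(sites)]
        assert kept == [2, 3]

    def test_truncate_policy_scales_to_cap(self):
        (out,) = list(trim_sites([sc(1, {"A": 3000, "G": 1500})], cap_policy="truncate"))
        assert out.total == 2000
        assert out.counts["A"] == pytest.approx(1333, abs=1)
        assert out.counts["A"] + out.counts["G"] == 2000

    def test_idempotent(self):
        sites = [sc(i, {"A": 10 + i}) for i in range(20)]
        once = list(trim_sites(sites))
        twice = list(trim_sites(once))
        assert [s.counts for s in twice] == [s.counts for s in once]

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            list(trim_sites([], min_cov=100, max_cov=50))


class TestConcordance:
    def test_identical_rows_retained_chi2_zero(self):
        a = sc(1, {"A": 50, "G": 50})
        b = sc(1, {"A": 50, "G": 50})
        res = replicate_concordance([a, b])
        assert res.retain and res.chi2 == pytest.approx(0.0) and res.df == 1

    def test_opposite_fixation_discarded(self):
        """Hand-computed Pearson chi-square of the 2x2 table
        [[100,0],[0,100]]: all four expected cells are 50, so
        chi2 = 4 * 50 = 200 on 1 df."""
        res = replicate_concordance([sc(1, {"A": 100, "G": 0}), sc(1, {"A": 0, "G": 100})])
        assert not res.retain
        assert res.chi2 == pytest.approx(200.0)
        assert res.df == 1
        assert res.p < 1e-40

    def test_monomorphic_trivially_retained(self):
        res = replicate_concordance([sc(1, {"A": 30}), sc(1, {"A": 60})])
        assert res.retain and res.df == 0

    def test_empty_replicate_discarded_with_reason(self):
        res = replicate_concordance([sc(1, {"A": 30}), sc(1, {"A": 0})])
        assert not res.retain and res.reason == "empty replicate"

    def test_low_expected_cells_retained_flagged(self):
        res = replicate_concordance([sc(1, {"A": 30, "G": 1}), sc(1, {"A": 30, "G": 0})])
        assert res.retain and res.reason == "low expected counts"

    def test_mismatched_sites_rejected(self):
        with pytest.raises(ValueError, match="different sites"):
            replicate_concordance([sc(1, {"A": 5}), sc(2, {"A": 5})])


class TestIntersections:
    def test_replicate_intersection_keys_and_sums(self):
        r1 = {s.key: s for s in [sc(1, {"A": 10}), sc(2, {"A": 10, "G": 5})]}
        r2 = {s.key: s for s in [sc(2, {"A": 12, "G": 6}), sc(3, {"A": 9})]}
        merged, tally = intersect_replicates(r1, r2)
        assert list(merged) == [("c1", 2)]
        assert merged[("c1", 2)].counts == {"A": 22, "G": 11}
        assert tally.n_in == 1 and tally.n_retained == 1

    def test_disjoint_replicates_empty(self):
        r1 = {s.key: s for s in [sc(1, {"A": 20})]}
        r2 = {s.key: s for s in [sc(2, {"A": 20})]}
        merged, _ = intersect_replicates(r1, r2)
        assert merged == {}

    def test_commutative_on_keys(self):
        r1 = {s.key: s for s in [sc(i, {"A": 30}) for i in (1, 2, 5)]}
        r2 = {s.key: s for s in [sc(i, {"A": 30}) for i in (2, 5, 9)]}
        ab, _ = intersect_replicates(r1, r2)
        ba, _ = intersect_replicates(r2, r1)
        assert set(ab) == set(ba)
        assert intersect_collections(ab, ba) == sorted(ab)

    def test_alt_allele_second_most_common_with_tiebreak(self):
        rows = [sc(1, {"A": 120, "G": 40, "T": 1})]
        assert pooled_alt_allele(rows, "A") == "G"
        tie = [sc(1, {"A": 100, "G": 10, "T": 10})]
        assert pooled_alt_allele(tie, "A") == "G"  # lexicographically smallest

    def test_build_contingency_rows_and_alt(self):
        rows_i = [("i_rep1", sc(1, {"A": 60, "G": 20})), ("i_rep2", sc(1, {"A": 55, "G": 25}))]
        rows_j = [("j_rep1", sc(1, {"A": 80})), ("j_rep2", sc(1, {"A": 70, "G": 2}))]
        table = build_contingency(("c1", 1), rows_i, rows_j)
        assert table.alt == "G"
        assert len(table.rows) == 4
        assert table.collection_counts("i_rep1").counts == {"A": 60, "G": 20}


class TestHandCountedFixture:
    def test_twenty_site_filter_cascade(self):
        """20 printed sites; survivors of each stage equal the hand count.

        Replicate 1 depths:  8 sites < 15 reads (removed), one site at
        2500 reads (repeat, removed), 11 pass trim.
        Replicate 2 shares 9 of those keys; one shared site has opposite
        fixation (discarded by concordance) -> 8 survive.
        """
        rep1 = {}
        for i in range(1, 9):  # under min coverage
            rep1[("c1", i)] = sc(i, {"A": 14})
        rep1[("c1", 9)] = sc(9, {"A": 2500})  # over cap
        for i in range(10, 21):  # 11 clean sites
            rep1[("c1", i)] = sc(i, {"A": 40, "G": 40})
        trimmed1 = {s.key: s for s in trim_sites(rep1.values())}
        assert len(trimmed1) == 11

        rep2 = {}
        for i in range(12, 21):  # 9 shared keys
            rep2[("c1", i)] = sc(i, {"A": 40, "G": 40})
        rep2[("c1", 12)] = sc(12, {"A": 80, "G": 0})  # discordant with rep1
        rep2[("c1", 30)] = sc(30, {"A": 40})  # unshared
        trimmed2 = {s.key: s for s in trim_sites(rep2.values())}

        merged, tally = intersect_replicates(trimmed1, trimmed2)
        assert tally.n_in == 9
        assert tally.n_discarded_concordance == 1
        assert len(merged) == 8


def _random_library_text(rng, n_sites=60, with_indels=True):
    lines = [HEADER]
    for i in range(n_sites):
        ref = "ACGT"[rng.integers(0, 4)]
        counts = {ref: int(rng.integers(0, 3000))}
        if rng.random() < 0.5:
            alt = "ACGT"[rng.integers(0, 4)]
            if alt != ref:
                counts[alt] = int(rng.integers(0, 100))
        if with_indels and rng.random() < 0.2:
            counts["+AG" if rng.random() < 0.5 else "-T"] = int(rng.integers(1, 20))
        total = sum(counts.values())
        if total == 0:
            continue
        pairs = "\t".join(f"{a}:{v}" for a, v in counts.items() if v > 0)
        lines.append(f"c1\t{i + 1}\t{ref}\t{total}\t{pairs}\n")
    return "".join(lines)


class TestVectorizedEquivalence:
    """The pandas LibraryTable path must reproduce the per-site semantics."""

    @pytest.mark.parametrize("cap_policy", ["exclude", "truncate"])
    def test_trim_agrees(self, tmp_path, cap_policy, rng):
        p = _write(tmp_path, _random_library_text(rng))
        object_path = list(trim_sites(read_readcounts(p), cap_policy=cap_policy))
        table = trim_table(read_readcounts_table(p), cap_policy=cap_policy)
        assert [s.position for s in object_path] == table.df["position"].tolist()
        got_totals = table.counts_matrix().sum(axis=1).tolist()
        assert [s.total for s in object_path] == got_totals

    def test_replicate_stage_agrees(self, tmp_path, rng):
        p1 = _write(tmp_path, _random_library_text(rng, 80), "r1.tsv")
        p2 = _write(tmp_path, _random_library_text(rng, 80), "r2.tsv")
        t1 = {s.key: s for s in trim_sites(read_readcounts(p1))}
        t2 = {s.key: s for s in trim_sites(read_readcounts(p2))}
        obj, obj_tally = intersect_replicates(t1, t2)

        v1 = trim_table(read_readcounts_table(p1))
        v2 = trim_table(read_readcounts_table(p2))
        vec, _, vec_tally = intersect_replicates_table([v1, v2])

        assert sorted(obj) == list(zip(vec.df["contig"], vec.df["position"]))
        assert obj_tally.n_discarded_concordance == vec_tally.n_discarded_concordance
        assert obj_tally.n_flagged_low_expected == vec_tally.n_flagged_low_expected
        for (_, posn), site in obj.items():
            row = vec.df[vec.df["position"] == posn].iloc[0]
            nuc_total = sum(v for a, v in site.counts.items() if a in "ACGT")
            assert row[["A", "C", "G", "T"]].sum() == nuc_total

    def test_collection_intersection_agrees(self, tmp_path, rng):
        pa = _write(tmp_path, _random_library_text(rng, 70), "a.tsv")
        pb = _write(tmp_path, _random_library_text(rng, 70), "b.tsv")
        ta = trim_table(read_readcounts_table(pa))
        tb = trim_table(read_readcounts_table(pb))
        merged = intersect_collections_table(ta, tb)
        sa = {s.key: s for s in trim_sites(read_readcounts(pa))}
        sb = {s.key: s for s in trim_sites(read_readcounts(pb))}
        assert intersect_collections(sa, sb) == sorted(
            zip(merged["contig"], merged["position"])
        )


@settings(max_examples=50, deadline=None)
@given(
    counts=st.lists(
        st.dictionaries(
            st.sampled_from(["A", "C", "G", "T", "+A", "-G"]),
            st.integers(min_value=0, max_value=5000),
            min_size=1,
            max_size=4,
        ),
        min_size=1,
        max_size=30,
    )
)
def test_trim_filter_idempotent_property(counts):
    sites = [sc(i + 1, c) for i, c in enumerate(counts)]
    once = list(trim_sites(sites, cap_policy="truncate"))
    twice = list(trim_sites(once, cap_policy="truncate"))
    assert [s.counts for s in twice] == [s.counts for s in once]
    assert all(15 <= s.total <= 2000 for s in once)
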