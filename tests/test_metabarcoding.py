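"""Tests for OTU-table post-processing, identity and greedy clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycomix import (
    InvalidInputError,
    ReadRecord,
    ReadSet,
    dominance_summary,
    filter_otu_table,
    greedy_cluster,
    pairwise_identity,
    relative_abundance,
)
from mycomix.metabarcoding import parse_size_annotation, round_half_up
from conftest import make_otu_table
from _oracles import brute_greedy_cluster, dp_identity

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterOtuTable:
    def test_singleton_otu_removed(self):
        table = make_otu_table({"g1": {"big": 100, "single": 1}})
        filtered = filter_otu_table(table, drop_singletons=True,
                                    guild_whitelist=None)
        assert filtered.otu_ids == ["big"]

    def test_high_count_otu_outside_whitelist_removed(self):
        table = make_otu_table(
            {"g1": {"keep": 10, "junk": 10_000}},
            otu_meta={
                "keep": ("Ceratobasidium", "Ceratobasidiaceae",
                         "orchid_mycorrhizal"),
                "junk": ("Trichoderma", "Hypocreaceae", "other"),
            },
        )
        filtered = filter_otu_table(
            table,
            drop_singletons=True,
            guild_whitelist={"orchid_mycorrhizal", "ectomycorrhizal",
                             "saprotrophic"},
        )
        assert filtered.otu_ids == ["keep"]

    def test_random_table_matches_bruteforce_set_filter(self):
        rng = np.random.default_rng(17)
        guilds = ("orchid_mycorrhizal", "ectomycorrhizal", "saprotrophic",
                  "other")
        counts = {f"g{j}": {} for j in range(3)}
        meta = {}
        for i in range(25):
            otu = f"otu{i:02d}"
            meta[otu] = ("G", "F", guilds[rng.integers(0, 4)])
            for g in counts:
                counts[g][otu] = int(rng.integers(0, 4))
        table = make_otu_table(counts, otu_meta=meta)
        whitelist = {"orchid_mycorrhizal", "saprotrophic"}
        filtered = filter_otu_table(table, drop_singletons=True,
                                    guild_whitelist=whitelist)
        # oracle: literal set filter over totals and guilds
        expected = {
            otu for otu in table.otu_ids
            if sum(counts[g][otu] for g in counts) != 1
            and meta[otu][2] in whitelist
        }
        assert set(filtered.otu_ids) == expected

    def test_everything_filtered_warns_not_raises(self):
        table = make_otu_table({"g1": {"only": 5}},
                               otu_meta={"only": ("G", "F", "other")})
        with pytest.warns(UserWarning, match="filtered out"):
            filtered = filter_otu_table(table, guild_whitelist={"saprotrophic"})
        assert filtered.otu_ids == []


# ---------------------------------------------------------------------------
# relative abundance & dominance
# ---------------------------------------------------------------------------

class TestRelativeAbundance:
    def test_published_phenotype_percentages(self, albino_protocorm_table):
        ra = relative_abundance(albino_protocorm_table, by="group")
        pct = {(r.unit, r.otu_id): r.percent for r in ra.itertuples(index=False)}
        assert pct[("albino", "OTU1")] == 98.87
        assert pct[("albino", "Russula")] == 0.95
        assert pct[("albino", "Sebacina")] == 0.18
        assert pct[("protocorm", "OTU1")] == 99.78
        assert pct[("protocorm", "Russula")] == 0.22

    def test_single_otu_unit_is_100(self):
        table = make_otu_table({"g1": {"solo": 7}})
        ra = relative_abundance(table, by="group")
        assert ra.percent.tolist() == [100.00]

    def test_rounded_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(23)
        counts = {f"g{j}": {f"otu{i}": int(rng.integers(1, 5000))
                            for i in range(9)} for j in range(4)}
        table = make_otu_table(counts)
        ra = relative_abundance(table, by="group")
        sums = ra.groupby("unit").percent.sum()
        assert ((sums - 100.0).abs() <= 0.02 + 1e-9).all()
        # exact before rounding
        exact = relative_abundance(table, by="group", ndigits=None)
        assert exact.groupby("unit").percent.sum().to_numpy() == pytest.approx(
            [100.0] * 4, abs=1e-9
        )

    def test_scale_invariance_after_filtering(self):
        counts = {"g1": {"a": 3, "b": 17, "c": 80}}
        t1 = make_otu_table(counts)
        t2 = make_otu_table({"g1": {k: 13 * v for k, v in counts["g1"].items()}})
        wl = {"orchid_mycorrhizal"}
        r1 = relative_abundance(filter_otu_table(t1, False, wl), by="group")
        r2 = relative_abundance(filter_otu_table(t2, False, wl), by="group")
        assert r1.percent.tolist() == r2.percent.tolist()

    def test_zero_total_unit_excluded_with_warning(self):
        table = make_otu_table({"full": {"a": 10}, "empty": {"a": 0}})
        with pytest.warns(UserWarning, match="zero reads"):
            ra = relative_abundance(table, by="group")
        assert set(ra.unit) == {"full"}

    def test_half_up_rounding_convention(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.985, 2) == 0.99


class TestDominanceSummary:
    def test_published_dominant_otus_cumulative(self):
        """The three dominant mycobiont OTUs jointly hold > 83 % of reads."""
        table = make_otu_table(
            {"oaf": {"OTU1": 9589, "OTU2": 10302, "OTU3": 1255,
                     "Clitopilus": 3928, "other": 168}},
        )
        dom = dominance_summary(table, by="group")
        assert dom.otu_id.tolist()[:3] == ["OTU2", "OTU1", "Clitopilus"]
        top3_cera = dom[dom.otu_id.isin(["OTU1", "OTU2", "OTU3"])].percent.sum()
        assert top3_cera > 83.0

    def test_single_otu_is_rank_one_at_100(self):
        table = make_otu_table({"g": {"a": 50}})
        dom = dominance_summary(table)
        assert dom.loc[0, "rank"] == 1
        assert dom.loc[0, "cumulative_percent"] == pytest.approx(100.0)

    def test_uniform_shares_have_linear_cumulative(self):
        k = 5
        table = make_otu_table({"g": {f"otu{i}": 100 for i in range(k)}})
        dom = dominance_summary(table)
        for row in dom.itertuples(index=False):
            assert row.cumulative_percent == pytest.approx(row.rank / k * 100)


# ---------------------------------------------------------------------------
# identity & clustering
# ---------------------------------------------------------------------------

class TestPairwiseIdentity:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACGT", "ACGT", 1.0),
        ("ACGT", "ACGA", 0.75),
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_substitutions_and_deletion_match_dp_oracle(self):
        rng = np.random.default_rng(40)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 40)])
        b = list(a)
        b[5] = "A" if b[5] != "A" else "C"
        b[20] = "G" if b[20] != "G" else "T"
        del b[30]
        b = "".join(b)
        assert pairwise_identity(a, b) == pytest.approx(dp_identity(a, b))

    @given(dna, dna)
    def test_matches_exhaustive_dp_on_random_pairs(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(dp_identity(a, b))

    @given(dna, dna)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @given(dna)
    def test_self_identity_is_one(self, a):
        assert pairwise_identity(a, a) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_identical_sequences_single_cluster(self):
        reads = ReadSet([
            ReadRecord("low", "ACGTACGT", 2),
            ReadRecord("high", "ACGTACGT", 9),
            ReadRecord("mid", "ACGTACGT", 5),
        ])
        res = greedy_cluster(reads, threshold=0.97)
        assert res.centroids == ["high"]
        assert set(res.membership.values()) == {"high"}

    def test_two_divergent_families_give_two_clusters(self):
        reads = ReadSet([
            ReadRecord("a1", "A" * 30, 10),
            ReadRecord("a2", "A" * 29 + "C", 3),
            ReadRecord("b1", "C" * 15 + "G" * 15, 8),
            ReadRecord("b2", "C" * 15 + "G" * 14 + "T", 2),
        ])
        res = greedy_cluster(reads, threshold=0.9)
        assert res.n_clusters == 2
        assert res.membership["a2"] == "a1"
        assert res.membership["b2"] == "b1"

    def test_matches_bruteforce_on_random_reads(self):
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        base_seq = bases[rng.integers(0, 4, 60)]
        records = []
        for i in range(10):
            seq = base_seq.copy()
            n_mut = int(rng.integers(0, 6))
            for p in rng.choice(60, size=n_mut, replace=False):
                seq[p] = bases[rng.integers(0, 4)]
            records.append(ReadRecord(f"r{i:02d}", "".join(seq),
                                      int(rng.integers(1, 50))))
        res = greedy_cluster(ReadSet(records), threshold=0.97)
        exp_centroids, exp_members = brute_greedy_cluster(records, 0.97)
        assert res.centroids == exp_centroids
        assert res.membership == exp_members

    def test_input_order_is_irrelevant(self):
        rng = np.random.default_rng(5)
        records = [
            ReadRecord(f"r{i}", "".join(np.array(list("ACGT"))[
                rng.integers(0, 4, 30)]), int(rng.integers(1, 20)))
            for i in range(8)
        ]
        res1 = greedy_cluster(ReadSet(records), threshold=0.8)
        res2 = greedy_cluster(ReadSet(records[::-1]), threshold=0.8)
        assert res1.centroids == res2.centroids
        assert res1.membership == res2.membership

    def test_members_satisfy_threshold_against_centroid(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        records = [
            ReadRecord(f"r{i}", "".join(bases[rng.integers(0, 4, 40)]),
                       int(rng.integers(1, 20)))
            for i in range(12)
        ]
        threshold = 0.5
        res = greedy_cluster(ReadSet(records), threshold=threshold)
        seqs = {r.read_id: r.sequence for r in records}
        for rid, cid in res.membership.items():
            assert pairwise_identity(seqs[rid], seqs[cid]) >= threshold

    def test_empty_read_set_rejected(self):
        with pytest.raises(InvalidInputError):
            greedy_cluster(ReadSet([]))


def test_size_annotation_parsing():
    assert parse_size_annotation("read1;size=42") == ("read1", 42)
    assert parse_size_annotation("read1;size=7;") == ("read1", 7)
    assert parse_size_annotation("plain_read") == ("plain_read", 1)
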