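"""UMI keying, family grouping, majority-vote collapsing and masking."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

import umicall as uc
from umicall.consensus import GroupingError, canonical_umi_key

from _oracles import connected_component_clusters, edit_distance_oracle


def make_read(bases, orientation="+", umi_a="AACGTAAC", umi_b="TTACGGCA",
              start=100, read_id="r", qual=30, chrom="chr1"):
    if isinstance(bases, str):
        bases = bases.encode()
    return uc.UmiRead(read_id=read_id, chrom=chrom, fragment_start=start,
                      fragment_end=start + len(bases),
                      orientation=orientation, umi_a=umi_a, umi_b=umi_b,
                      bases=bases, base_qualities=bytes([qual]) * len(bases))


class TestCanonicalKey:
    def test_reciprocal_pairs_share_key_with_opposite_strands(self):
        k1, s1 = canonical_umi_key("AACGT", "TTACG", "+")
        k2, s2 = canonical_umi_key("TTACG", "AACGT", "-")
        assert k1 == k2
        assert (s1, s2) == ("+", "-")

    def test_palindromic_pair_is_well_defined(self):
        k1, _ = canonical_umi_key("AAAAA", "AAAAA", "+")
        k2, _ = canonical_umi_key("AAAAA", "AAAAA", "-")
        assert k1 == k2 == "AAAAA-AAAAA"

    def test_exhaustive_fixed_pool_symmetry(self):
        rng = np.random.default_rng(0)
        pool = ["".join("ACGT"[c] for c in rng.integers(0, 4, 8))
                for _ in range(32)]
        for a in pool:
            for b in pool:
                kf, sf = canonical_umi_key(a, b, "+")
                kr, sr = canonical_umi_key(b, a, "-")
                assert kf == kr and (sf, sr) == ("+", "-")

    def test_empty_umi_rejected(self):
        with pytest.raises(ValueError):
            canonical_umi_key("", "ACGT", "+")


class TestGrouping:
    def test_edit_distance_merges_near_keys(self):
        r1 = make_read("ACGTACGT", umi_a="AAAAAAAA", umi_b="CCCCCCCC")
        r2 = make_read("ACGTACGT", umi_a="AAAAAAAT", umi_b="CCCCCCCC")
        assert len(uc.group_duplicates([r1, r2], max_edit_distance=2)) == 1
        assert len(uc.group_duplicates([r1, r2], max_edit_distance=0)) == 2

    def test_distance_zero_equals_exact_hashing(self):
        rng = np.random.default_rng(1)
        reads = []
        for i in range(60):
            umi_a = "".join("ACGT"[c] for c in rng.integers(0, 4, 5))
            umi_b = "".join("ACGT"[c] for c in rng.integers(0, 4, 5))
            orientation = "+" if rng.random() < 0.5 else "-"
            reads.append(make_read("ACGT" * 5, orientation=orientation,
                                   umi_a=umi_a, umi_b=umi_b,
                                   read_id=f"r{i}"))
        families = uc.group_duplicates(reads, max_edit_distance=0)
        expected = {}
        for read in reads:
            key, _ = canonical_umi_key(read.umi_a, read.umi_b, read.orientation)
            expected.setdefault(key, set()).add(read.read_id)
        got = {frozenset(r.read_id for r in f.forward_members
                         + f.reverse_members) for f in families}
        assert got == {frozenset(v) for v in expected.values()}

    def test_corrupted_umis_recover_molecules(self):
        """Single-base UMI corruptions regroup to truth; matches the
        all-pairs edit-distance clustering oracle."""
        rng = np.random.default_rng(2)
        # four molecules with mutually distant UMI pairs
        pairs = [("AAAAAAAA", "CCCCCCCC"), ("GGGGGGGG", "TTTTTTTT"),
                 ("ACACACAC", "GTGTGTGT"), ("AAGGAAGG", "CCTTCCTT")]
        reads, truth = [], []
        for mol, (ua, ub) in enumerate(pairs):
            for j in range(5):
                a, b = ua, ub
                if j == 1:  # one corrupted copy per molecule
                    a = "T" + a[1:]
                orientation = "+" if j % 2 == 0 else "-"
                if orientation == "-":
                    a, b = b, a
                reads.append(make_read("ACGTACGT", orientation=orientation,
                                       umi_a=a, umi_b=b,
                                       read_id=f"m{mol}r{j}"))
                truth.append(mol)
        families = uc.group_duplicates(reads, max_edit_distance=2)
        got = sorted(sorted(int(r.read_id[1]) for r in f.forward_members
                            + f.reverse_members) for f in families)
        assert got == [[0] * 5, [1] * 5, [2] * 5, [3] * 5]
        # oracle: transitive-closure clustering over canonical keys
        keys = [canonical_umi_key(r.umi_a, r.umi_b, r.orientation)[0]
                for r in reads]
        oracle = connected_component_clusters(keys, 2)
        oracle_parts = sorted(sorted(truth[i] for i in c) for c in oracle)
        assert oracle_parts == [[0] * 5, [1] * 5, [2] * 5, [3] * 5]

    def test_unsorted_input_rejected(self):
        r1 = make_read("ACGT", start=200, read_id="a")
        r2 = make_read("ACGT", start=100, read_id="b")
        with pytest.raises(GroupingError):
            uc.group_duplicates([r1, r2])

    def test_reads_without_umis_skipped(self):
        r1 = make_read("ACGT", read_id="good")
        r2 = make_read("ACGT", umi_a="", umi_b="", read_id="bad")
        families = uc.group_duplicates([r1, r2])
        assert sum(f.family_size for f in families) == 1


class TestBuildConsensus:
    def test_identical_members_reproduce_read(self):
        fam = uc.group_duplicates([make_read("ACGTACGTAC", read_id=f"r{i}")
                                   for i in range(4)])[0]
        cons = uc.build_consensus(fam)
        assert cons.bases == b"ACGTACGTAC"
        assert set(cons.joint_qualities) == {30}
        assert cons.family_size == 4 and cons.stratum == 4
        assert cons.duplex_flag == 0

    def test_concordance_boundary_three_of_four_kept(self):
        reads = [make_read("AAAA", read_id=f"r{i}") for i in range(3)]
        reads.append(make_read("ACAA", read_id="r3"))  # 3/4 = 75% at column 1
        fam = uc.group_duplicates(reads)[0]
        cons = uc.build_consensus(fam, max_discordant_fraction=1.0)
        assert cons.bases == b"AAAA"  # 75% is not < 75%

    def test_fifty_percent_concordance_masked(self):
        reads = [make_read("AAAA", read_id="r0"), make_read("ACAA", read_id="r1")]
        fam = uc.group_duplicates(reads)[0]
        cons = uc.build_consensus(fam, max_discordant_fraction=1.0)
        assert cons.bases == b"ANAA"
        from umicall.consensus import MASK_QUALITY
        assert cons.joint_qualities[1] == MASK_QUALITY

    def test_duplex_strand_disagreement_masked(self):
        fwd = [make_read("AAAA", "+", read_id=f"f{i}") for i in range(2)]
        rev = [make_read("AGAA", "-", umi_a="TTACGGCA", umi_b="AACGTAAC",
                         read_id=f"v{i}") for i in range(2)]
        fam = uc.group_duplicates(fwd + rev)[0]
        assert fam.family_size == 4
        cons = uc.build_consensus(fam, max_discordant_fraction=1.0)
        assert cons.duplex_flag == 1
        assert cons.bases == b"ANAA"

    def test_duplex_needs_both_strands(self):
        fwd = [make_read("AAAA", "+", read_id=f"f{i}") for i in range(4)]
        cons = uc.build_consensus(uc.group_duplicates(fwd)[0])
        assert cons.duplex_flag == 0

    def test_discordant_member_removed_and_revoted(self):
        reads = [make_read("A" * 40, read_id=f"r{i}") for i in range(3)]
        garbage = "C" * 8 + "A" * 32  # 20% discordant
        reads.append(make_read(garbage, read_id="r3"))
        fam = uc.group_duplicates(reads)[0]
        cons = uc.build_consensus(fam, max_discordant_fraction=0.05)
        assert cons.bases == b"A" * 40  # no residual masking after re-vote
        assert cons.family_size == 3

    def test_all_members_discordant_returns_none(self):
        reads = [make_read("AAAACCCC", read_id="r0"),
                 make_read("CCCCGGGG", read_id="r1"),
                 make_read("GGGGAAAA", read_id="r2")]
        fam = uc.group_duplicates(reads)[0]
        assert uc.build_consensus(fam, max_discordant_fraction=0.05) is None

    def test_joint_quality_is_mean_of_concordant(self):
        reads = [make_read("AAAA", qual=20, read_id="r0"),
                 make_read("AAAA", qual=40, read_id="r1"),
                 make_read("AAAA", qual=31, read_id="r2")]
        fam = uc.group_duplicates(reads)[0]
        cons = uc.build_consensus(fam)
        assert cons.joint_qualities == bytes([round((20 + 40 + 31) / 3)]) * 4

    def test_incompatible_lengths_raise(self):
        fam = uc.ReadFamily(("chr1", 100, 104, "k"),
                            [make_read("ACGT"), make_read("ACGTA")], [])
        with pytest.raises(GroupingError):
            uc.build_consensus(fam)

    @given(st.integers(1, 6), st.text(alphabet="ACGT", min_size=5, max_size=30))
    def test_idempotence_property(self, k, seq):
        reads = [make_read(seq, read_id=f"r{i}") for i in range(k)]
        cons = uc.build_consensus(uc.group_duplicates(reads)[0])
        assert cons.bases == seq.encode()
        assert cons.family_size == k and cons.stratum == min(k, 4)


class TestCollapseAll:
    def test_family_size_conservation(self, mixed_pipeline):
        sim = mixed_pipeline.sim
        families = uc.group_duplicates(sim.reads, 3)
        assert sum(f.family_size for f in families) == len(sim.reads)

    def test_mc_count_matches_truth_molecules(self):
        cfg = uc.SimConfig(n_targets=3, reference_length=8_000,
                           input_genome_equivalents=300, umi_error_rate=0.0,
                           rng_seed=9)
        sim = uc.simulate(cfg)
        cons, summary = uc.collapse_all(sim.reads, uc.ConsensusParams())
        assert len(cons) == len(sim.molecules)
        assert summary["total"].sum() == len(sim.molecules)

    def test_duplex_set_matches_truth_emissions(self):
        cfg = uc.SimConfig(n_targets=3, reference_length=8_000,
                           input_genome_equivalents=300, umi_error_rate=0.0,
                           rng_seed=10)
        sim = uc.simulate(cfg)
        cons, _ = uc.collapse_all(sim.reads, uc.ConsensusParams())
        truth_both = {m for m, _ in sim.emissions}
        truth_both = {m for m in truth_both
                      if (m, "+") in sim.emissions and (m, "-") in sim.emissions}
        n_duplex = sum(c.duplex_flag for c in cons)
        assert n_duplex == len(truth_both)

    def test_dc_mode_drops_simplex(self):
        cfg = uc.SimConfig(n_targets=2, reference_length=6_000,
                           input_genome_equivalents=200, rng_seed=11)
        sim = uc.simulate(cfg)
        mc, _ = uc.collapse_all(sim.reads, uc.ConsensusParams(mode="MC"))
        dc, _ = uc.collapse_all(sim.reads, uc.ConsensusParams(mode="DC"))
        assert len(dc) == sum(c.duplex_flag for c in mc)
        assert all(c.duplex_flag == 1 for c in dc)

    def test_empty_input(self):
        cons, summary = uc.collapse_all([], uc.ConsensusParams())
        assert cons == [] and summary["total"].sum() == 0
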