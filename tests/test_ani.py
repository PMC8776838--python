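"""Fragment ANI: windowing, mapping identity, species clustering, length estimator."""

import numpy as np
import pytest

from sidescan.ani import (
    AniResult,
    MagAssembly,
    ReferenceIndex,
    cluster_species,
    compute_ani,
    estimate_species_genome_length,
    fragment_genome,
    map_fragment,
    pairwise_ani,
)
from sidescan.simulate import SimConfig, gen_genome, mutate_genome


def random_seq(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


class TestFragmentGenome:
    @pytest.mark.parametrize(
        "lengths,expected",
        [((4500,), 3), ((1499,), 0), ((3000, 1600), 3), ((), 0)],
    )
    def test_window_counts(self, lengths, expected):
        contigs = {f"c{i}": random_seq(i, n) for i, n in enumerate(lengths)}
        assert len(fragment_genome(contigs, 1500)) == expected

    def test_fragment_length_positive(self):
        with pytest.raises(ValueError):
            fragment_genome({"c": "ACGT"}, 0)


class TestMapFragment:
    def test_verbatim_fragment_maps_at_100(self):
        ref = random_seq(1, 50_000)
        index = ReferenceIndex({"c1": ref})
        assert map_fragment(ref[10_000:11_500], index) == pytest.approx(1.0)

    def test_substitution_identity_exact(self):
        # 15 substitutions over 1500 bp -> 99.0% identity
        ref = random_seq(2, 50_000)
        frag = list(ref[3_000:4_500])
        rng = np.random.default_rng(3)
        for pos in rng.choice(1500, size=15, replace=False):
            frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
        ident = map_fragment("".join(frag), ReferenceIndex({"c1": ref}))
        assert ident == pytest.approx(0.99, abs=1e-9)

    def test_unrelated_fragment_unmapped(self):
        ref = random_seq(4, 50_000)
        frag = random_seq(5, 1500)
        assert map_fragment(frag, ReferenceIndex({"c1": ref})) is None


class TestComputeAni:
    def test_self_ani_is_100(self):
        g = gen_genome(SimConfig(seed=1, genome_length=20_000, n_genes=5, cluster_spec=()))
        mag = MagAssembly("A", {"c1": g.sequence})
        res = compute_ani(mag, mag)
        assert res.ani == pytest.approx(100.0) and res.aligned_fraction == 1.0

    def test_three_percent_mutant_near_97(self):
        seq = random_seq(7, 100_000)
        mut = mutate_genome(seq, 0.03, seed=8)
        res = compute_ani(MagAssembly("B", {"c1": mut}), MagAssembly("A", {"c1": seq}))
        assert res.ani == pytest.approx(97.0, abs=0.5)

    def test_matches_positionwise_oracle(self):
        seq = random_seq(9, 100_000)
        mut = mutate_genome(seq, 0.03, seed=10)
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(mut.encode(), dtype=np.uint8)
        n_frag = len(seq) // 1500
        oracle = 100 * np.mean(
            [
                1 - np.mean(a[i * 1500 : (i + 1) * 1500] != b[i * 1500 : (i + 1) * 1500])
                for i in range(n_frag)
            ]
        )
        res = compute_ani(MagAssembly("B", {"c1": mut}), MagAssembly("A", {"c1": seq}))
        assert res.ani == pytest.approx(oracle, abs=0.1)

    def test_unrelated_genomes_undefined(self):
        res = compute_ani(
            MagAssembly("A", {"c1": random_seq(11, 10_000)}),
            MagAssembly("B", {"c1": random_seq(12, 10_000)}),
        )
        assert not res.defined and res.aligned_fraction == 0.0

    def test_too_short_genome_flagged(self):
        res = compute_ani(
            MagAssembly("A", {"c1": random_seq(13, 800)}),
            MagAssembly("B", {"c1": random_seq(14, 10_000)}),
        )
        assert not res.defined and res.n_fragments == 0


def ani_pair(a, b, value):
    return AniResult(a, b, value, 1.0, 10, 10)


class TestClusterSpecies:
    def make_mags(self, ids):
        return [MagAssembly(i, {"c": "A" * 2000}, 1.0) for i in ids]

    def test_four_members_plus_outgroup(self):
        mags = self.make_mags(list("ABCDE"))
        results = []
        for x in "ABCD":
            for y in "ABCD":
                if x != y:
                    results.append(ani_pair(x, y, 96.5))
        groups = cluster_species(mags, results, threshold_percent=95.0)
        sizes = sorted(len(g.member_mag_ids) for g in groups)
        assert sizes == [1, 4]

    def test_all_below_threshold_all_singletons(self):
        mags = self.make_mags(list("ABC"))
        results = [ani_pair(a, b, 90.0) for a in "ABC" for b in "ABC" if a != b]
        groups = cluster_species(mags, results, 95.0)
        assert all(len(g.member_mag_ids) == 1 for g in groups)

    def test_single_linkage_chain(self):
        mags = self.make_mags(list("ABC"))
        results = [
            ani_pair("A", "B", 96.0), ani_pair("B", "C", 96.0),
            ani_pair("A", "C", 94.0),
        ]
        groups = cluster_species(mags, results, 95.0)
        assert len(groups) == 1 and set(groups[0].member_mag_ids) == {"A", "B", "C"}

    def test_complete_linkage_splits_chain(self):
        mags = self.make_mags(list("ABC"))
        results = [
            ani_pair("A", "B", 96.0), ani_pair("B", "C", 96.0),
            ani_pair("A", "C", 94.0),
        ]
        groups = cluster_species(mags, results, 95.0, linkage="complete")
        assert sorted(len(g.member_mag_ids) for g in groups) == [1, 2]

    def test_asymmetry_resolved_by_max(self):
        mags = self.make_mags(list("AB"))
        results = [ani_pair("A", "B", 94.0), ani_pair("B", "A", 96.0)]
        groups = cluster_species(mags, results, 95.0)
        assert len(groups) == 1

    def test_threshold_monotonicity_never_merges(self):
        mags = self.make_mags(list("ABCD"))
        rng = np.random.default_rng(0)
        results = [
            ani_pair(a, b, float(rng.uniform(93, 99)))
            for a in "ABCD" for b in "ABCD" if a != b
        ]
        prev = None
        for threshold in (94.0, 95.0, 96.0, 97.0, 98.0):
            groups = cluster_species(mags, results, threshold)
            assignment = {
                m: g.species_id for g in groups for m in g.member_mag_ids
            }
            if prev is not None:
                # same group now => was same group at the lower threshold
                for a in "ABCD":
                    for b in "ABCD":
                        if assignment[a] == assignment[b]:
                            assert prev[a] == prev[b]
            prev = assignment


class TestGenomeLengthEstimator:
    def test_complete_mag_identical_in_both_modes(self):
        mag = MagAssembly("A", {"c": "A" * 4000}, 1.0)
        assert estimate_species_genome_length([mag], "completeness_corrected") == 4000
        assert estimate_species_genome_length([mag], "as_printed") == 4000

    def test_half_complete_mag(self):
        mag = MagAssembly("A", {"c": "A" * 2000}, 0.5)
        assert estimate_species_genome_length([mag], "completeness_corrected") == 4000
        assert estimate_species_genome_length([mag], "as_printed") == 1000

    def test_two_member_mean(self):
        mags = [
            MagAssembly("A", {"c": "A" * 3000}, 0.75),
            MagAssembly("B", {"c": "A" * 4000}, 1.0),
        ]
        assert estimate_species_genome_length(mags) == pytest.approx(4000.0)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            estimate_species_genome_length([])


def test_pairwise_ani_mutant_family():
    """Mutated copies of one ancestor form one species; outgroup stays out."""
    ancestor = random_seq(21, 30_000)
    mags = [
        MagAssembly(f"M{i}", {"c1": mutate_genome(ancestor, 0.01, seed=100 + i)})
        for i in range(3)
    ] + [MagAssembly("OUT", {"c1": random_seq(22, 30_000)})]
    results = pairwise_ani(mags)
    with pytest.warns(UserWarning):  # OUT pairs undefined -> no edge
        groups = cluster_species(mags, results, 95.0)
    by_size = sorted(groups, key=lambda g: len(g.member_mag_ids))
    assert [len(g.member_mag_ids) for g in by_size] == [1, 3]
    assert by_size[0].member_mag_ids == ("OUT",)
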