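"""Neighbor joining, bootstrap support, and the two-stage HGT screen."""

import numpy as np
import pytest

import helpers
from sua5kit.align import star_msa
from sua5kit.annotation import reference_pair
from sua5kit.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    clade_placement_check,
    distance_matrix,
    first_divergence_rank,
    hgt_screen,
    mixed_taxa,
    nearest_neighbor_screen,
    neighbor_joining,
)
from sua5kit.records import InputError, ProteinRecord
from sua5kit.simulate import (
    SyntheticDatasetSpec,
    evolve_sequences,
    inject_hgt,
)


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        recs = [ProteinRecord(f"s{i}", "KRSNWPGMHYKRSNW") for i in range(3)]
        dm = distance_matrix(recs)
        assert np.allclose(dm.data, 0.0)

    def test_distance_is_one_minus_identity_fraction(self):
        a = ProteinRecord("a", "KRSN")
        b = ProteinRecord("b", "KRSD")
        c = ProteinRecord("c", "KRSN")
        dm = distance_matrix([a, b, c])
        assert dm.data[0, 1] == pytest.approx(0.25)
        assert dm.data[0, 2] == 0.0

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord("x", "KRSN"), ProteinRecord("x", "KRSD"),
                ProteinRecord("y", "KRSN")]
        with pytest.raises(InputError):
            distance_matrix(recs)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 0.1, 0.2], [0.3, 0, 0.1], [0.2, 0.1, 0]])
        with pytest.raises(InputError):
            DistanceMatrix(["a", "b", "c"], m)

    def test_correlates_with_true_path_length(self, small_dataset):
        dm = distance_matrix(small_dataset.records)
        tip_d = small_dataset.tree.tip_tip_distances()
        est, true = [], []
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                est.append(dm.data[i, j])
                true.append(float(tip_d[a, dm.ids[j]]))
        rho = np.corrcoef(est, true)[0, 1]
        assert rho > 0.9


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A,B),(C,D)) with branch lengths 1,2,3,4 and internal 5
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # branch lengths are exact on additive input
        tip_d = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                assert float(tip_d[a, ids[j]]) == pytest.approx(d[i, j])

    def test_equal_distances_resolve_deterministically(self):
        ids = list("ABCD")
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(ids, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(ids, d.copy()))
        assert str(t1) == str(t2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(4):
            edges, lengths, leaves = helpers.random_additive_tree(n_taxa, rng)
            d = helpers.tree_distances(edges, lengths, leaves)
            tree = neighbor_joining(DistanceMatrix(leaves, d))
            assert bipartitions(tree) == helpers.tree_splits(edges, leaves)

    def test_matches_exhaustive_least_squares_on_five_taxa(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            edges, lengths, leaves = helpers.random_additive_tree(5, rng)
            d = helpers.tree_distances(edges, lengths, leaves)
            nj_splits = bipartitions(neighbor_joining(DistanceMatrix(leaves, d)))
            assert nj_splits == helpers.least_squares_topology(d, leaves)

    def test_agrees_with_skbio_nj_topology(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        edges, lengths, leaves = helpers.random_additive_tree(7, rng)
        d = helpers.tree_distances(edges, lengths, leaves)
        dm = DistanceMatrix(leaves, d)
        ours = bipartitions(neighbor_joining(dm))
        theirs = bipartitions(skbio_nj(dm.to_skbio()))
        assert ours == theirs


class TestBootstrap:
    def _msa(self, seed, subst=0.12):
        sua5_t = ProteinRecord(
            "t", reference_pair()[0].sequence, truth_variant="Sua5"
        )
        ds = evolve_sequences(
            sua5_t,
            SyntheticDatasetSpec(n_taxa=8, subst_rate=subst, indel_rate=0.0, seed=seed),
        )
        msa = star_msa(
            [(r.id, r.sequence) for r in ds.records],
            reference_pair()[0].sequence,
        )
        return ds, msa

    def test_identical_rows_have_full_support_by_convention(self):
        ref = reference_pair()[0].sequence
        msa = star_msa([(f"r{i}", ref) for i in range(4)], ref)
        _, supports = bootstrap_support(msa, reps=10, seed=1)
        assert all(v == 100.0 for v in supports.values())

    def test_separating_bipartition_strongly_supported(self):
        ds, msa = self._msa(seed=51)
        tree, supports = bootstrap_support(msa, reps=100, seed=9)
        # the deepest split of the generating tree (two 4-leaf clades)
        left = frozenset(f"t{i:03d}" for i in range(4))
        leaves = frozenset(msa.ids)
        key = left if min(leaves) not in left else leaves - left
        assert key in supports
        assert supports[key] >= 95.0

    def test_same_seed_reproduces_supports(self):
        _, msa = self._msa(seed=52)
        _, s1 = bootstrap_support(msa, reps=50, seed=3)
        _, s2 = bootstrap_support(msa, reps=50, seed=3)
        assert s1 == s2

    def test_zero_reps_rejected(self):
        _, msa = self._msa(seed=53)
        with pytest.raises(InputError):
            bootstrap_support(msa, reps=0, seed=1)


class TestMixedTaxa:
    def test_single_variant_dataset_gives_empty_list(self):
        variants = {f"r{i}": "Sua5" for i in range(6)}
        taxa = {f"r{i}": ("bact", f"phy{i % 2}", "c", "s") for i in range(6)}
        assert mixed_taxa(variants, taxa, rank=1) == {}

    def test_injected_minority_variant_flags_the_group(self):
        variants = {"a": "Sua5", "b": "Sua5", "c": "TsaC", "d": "TsaC"}
        taxa = {
            "a": ("bact", "phyA"), "b": ("bact", "phyA"),
            "c": ("bact", "phyA"), "d": ("bact", "phyB"),
        }
        mixed = mixed_taxa(variants, taxa, rank=1)
        assert list(mixed) == ["phyA"]
        assert mixed["phyA"] == {"Sua5": 2, "TsaC": 1}

    def test_atypical_counts_as_sua5_user(self):
        variants = {"a": "atypical_sua5", "b": "TsaC"}
        taxa = {"a": ("arch", "phyX"), "b": ("arch", "phyX")}
        assert "phyX" in mixed_taxa(variants, taxa, rank=1)


class TestHgtScreen:
    def test_first_divergence_rank(self):
        assert first_divergence_rank(("d", "p", "c"), ("d", "p", "c")) is None
        assert first_divergence_rank(("d", "p1", "c"), ("d", "p2", "c")) == 1
        assert first_divergence_rank(("d1", "p", "c"), ("d2", "p", "c")) == 0

    def test_clonal_dataset_yields_no_candidates(self):
        recs = [
            ProteinRecord(f"r{i}", "KRSNWPGMHY" * 4, taxon_path=("d", "p", "c", f"s{i}"))
            for i in range(4)
        ]
        assert nearest_neighbor_screen(recs, 1) == []

    def test_planted_transfers_recovered_exactly(self, hgt_dataset):
        confirmed_expected = {r for r, _ in hgt_dataset.hgt_truth}
        candidates, _ = hgt_screen(hgt_dataset.records, 1)
        confirmed = {c.record_id for c in candidates if c.placement_confirmed}
        assert confirmed == confirmed_expected
        # stage-1 candidates must at least contain every recipient
        assert confirmed_expected <= {c.record_id for c in candidates}

    def test_no_transfer_control_confirms_nothing(self, small_dataset):
        candidates, _ = hgt_screen(small_dataset.records, 1)
        assert all(not c.placement_confirmed for c in candidates)

    def test_verbatim_copy_reports_full_identity(self, small_dataset):
        ds = inject_hgt(small_dataset, 1, divergence_rank=1, seed=3, noise=0.0)
        recipient = ds.hgt_truth[0][0]
        candidates, _ = hgt_screen(ds.records, 1)
        cand = {c.record_id: c for c in candidates}[recipient]
        assert cand.identity == 100.0

    def test_candidate_inside_own_clade_not_confirmed(self, small_dataset):
        from sua5kit.phylo import HGTCandidate, identity_matrix

        ids, m = identity_matrix(small_dataset.records)
        tree = neighbor_joining(DistanceMatrix(ids, 1.0 - m))
        rec = small_dataset.records[0]
        fake = HGTCandidate(
            record_id=rec.id,
            own_taxon=rec.taxon_path,
            neighbor_id=small_dataset.records[1].id,
            neighbor_taxon=small_dataset.records[1].taxon_path,
            identity=90.0,
            rank_of_divergence=1,
        )
        out = clade_placement_check(
            tree, fake, small_dataset.taxa_by_id(), 1
        )
        assert out.placement_confirmed is False

    def test_missing_leaf_rejected(self, small_dataset):
        from sua5kit.phylo import HGTCandidate, identity_matrix

        ids, m = identity_matrix(small_dataset.records)
        tree = neighbor_joining(DistanceMatrix(ids, 1.0 - m))
        ghost = HGTCandidate("nope", ("d",), "x", ("d",), 50.0, 0)
        with pytest.raises(InputError):
            clade_placement_check(tree, ghost, small_dataset.taxa_by_id(), 1)
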