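"""Maximal dependence decomposition: chi-square machinery and clustering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sglut.mdd import (
    AAGrouping,
    ContingencyTable,
    DEFAULT_GROUPING,
    GROUP_ORDER,
    best_split,
    chi_square,
    contingency,
    leaf_logo,
    mdd_cluster,
    position_score,
)
from sglut.seq_data import AA_ORDER, site_fragments
from sglut.synthetic import MotifSpec, SyntheticConfig, generate_records

from .conftest import make_fragment, random_fragment


def brute_force_chi_square(counts: np.ndarray) -> float:
    """Independent cell-by-cell oracle for the chi-square statistic."""
    total = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    out = 0.0
    for m in range(counts.shape[0]):
        for n in range(counts.shape[1]):
            expected = row[m] * col[n] / total
            if expected > 0:
                out += (counts[m, n] - expected) ** 2 / expected
    return out


class TestGrouping:
    def test_default_partition_covers_all_residues_disjointly(self):
        grouping = AAGrouping.default()
        assert set(DEFAULT_GROUPING) == set(AA_ORDER)
        seen = [grouping.mapping[aa] for aa in AA_ORDER]
        assert set(seen) == set(GROUP_ORDER)
        assert grouping.group_index("X") == -1

    def test_missing_residue_rejected(self):
        partial = {aa: "polar" for aa in AA_ORDER[:-1]}
        with pytest.raises(ValueError, match="without a group"):
            AAGrouping(partial)

    def test_grouping_file_round_trip(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("\n".join(f"{aa}\t{g}" for aa, g in DEFAULT_GROUPING.items()))
        assert AAGrouping.from_tsv(path).mapping == DEFAULT_GROUPING


class TestChiSquare:
    def test_two_group_diagonal_table_scores_twenty(self):
        counts = np.zeros((5, 5))
        counts[0, 0] = 10
        counts[1, 1] = 10
        assert chi_square(ContingencyTable(counts)) == pytest.approx(20.0)

    def test_independent_table_scores_zero(self):
        row = np.array([4.0, 8.0, 0.0, 2.0, 6.0])
        col = np.array([10.0, 0.0, 5.0, 2.0, 3.0])
        counts = np.outer(row, col) / col.sum()
        assert chi_square(ContingencyTable(counts)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 30, size=(5, 5)).astype(float)
            if counts.sum() == 0:
                continue
            assert chi_square(ContingencyTable(counts)) == pytest.approx(
                brute_force_chi_square(counts), abs=1e-9
            )

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            chi_square(ContingencyTable(np.zeros((5, 5))))

    def test_degrees_of_freedom_is_sixteen(self):
        assert ContingencyTable(np.ones((5, 5))).degrees_of_freedom == 16


class TestContingency:
    def test_planted_pair_fills_single_cell(self):
        frags = [make_fragment("K" + "A" * 4 + "C" + "A" * 4 + "D")] * 10
        table = contingency(frags, -5, 5)
        basic, acidic = GROUP_ORDER.index("basic"), GROUP_ORDER.index("acidic")
        assert table.counts[basic, acidic] == 10
        assert table.total == 10

    def test_pad_positions_drop_fragments_without_touching_others(self):
        clean = make_fragment("K" + "A" * 4 + "C" + "A" * 4 + "D")
        padded = make_fragment("X" + "A" * 4 + "C" + "A" * 4 + "D")
        table = contingency([clean, clean, padded], -5, 5)
        assert table.total == 2


class TestPositionScore:
    def test_score_sums_pairwise_chi_square_symmetrically(self, rng):
        frags = [random_fragment(rng, n=3) for _ in range(40)]
        chi_ij = chi_square(contingency(frags, -1, 2))
        # the (i, j) term appears in both Score(i) and Score(j)
        score_i = position_score(frags, -1)
        score_j = position_score(frags, 2)
        others_i = sum(
            chi_square(contingency(frags, -1, j))
            for j in (-3, -2, 1, 3)
        )
        assert score_i == pytest.approx(others_i + chi_ij)
        assert score_j >= chi_ij

    def test_planted_co_occurrence_dominates_scores(self):
        cfg = SyntheticConfig(
            n_proteins=100, positives_per_protein=2, negatives_per_protein=2,
            motifs=(MotifSpec(-6, residues="KR", penetrance=1.0),
                    MotifSpec(8, residues="DE", penetrance=1.0)),
            seed=0,
        )
        pos = [f for f in site_fragments(generate_records(cfg).proteins)
               if f.label == "positive"]
        scores = {i: position_score(pos, i) for i in range(-10, 11) if i != 0}
        top_two = sorted(scores, key=scores.get, reverse=True)[:2]
        assert set(top_two) == {-6, 8}


class TestBestSplit:
    def test_no_dependence_returns_none(self, rng):
        frags = [random_fragment(rng, n=4) for _ in range(60)]
        assert best_split(frags, threshold=80.0) is None

    def test_recovers_planted_motif(self, two_motif_positives):
        split = best_split(two_motif_positives)
        assert split is not None
        pos, group = split
        assert (pos, group) in {(-6, "basic"), (8, "acidic")}

    def test_deterministic(self, two_motif_positives):
        assert best_split(two_motif_positives) == best_split(two_motif_positives)


class TestMDDCluster:
    def test_identical_fragments_stay_one_leaf(self):
        frags = [make_fragment("K" + "A" * 4 + "C" + "A" * 5)] * 100
        tree = mdd_cluster(frags, max_cluster_size=10)
        assert len(tree.leaves) == 1
        assert tree.leaves[0].name == "GSH1"

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mdd_cluster([])

    def test_two_motif_set_splits_on_a_planted_motif(self, two_motif_positives):
        tree = mdd_cluster(two_motif_positives, max_cluster_size=100)
        assert len(tree.leaves) >= 2
        root_pos, root_group = tree.root.split
        assert (root_pos, root_group) in {(-6, "basic"), (8, "acidic")}
        # leaves partition the input
        members = [f for leaf in tree.leaves for f in leaf.fragments]
        assert len(members) == len(two_motif_positives)
        assert {id(f) for f in members} == {id(f) for f in two_motif_positives}

    def test_partial_penetrance_same_group_motifs_give_deeper_tree(self):
        # two basic motifs carried by distinct sub-populations at 90%
        # penetrance: the tree must isolate at least one planted motif at
        # the root and keep decomposing the mixed remainder
        cfg = SyntheticConfig(
            n_proteins=150, positives_per_protein=2, negatives_per_protein=2,
            motifs=(MotifSpec(-6, group="basic", penetrance=0.9),
                    MotifSpec(8, group="basic", penetrance=0.9)),
            seed=0,
        )
        pos = [f for f in site_fragments(generate_records(cfg).proteins)
               if f.label == "positive"]
        tree = mdd_cluster(pos, max_cluster_size=50)
        assert len(tree.leaves) >= 3
        root_pos, root_group = tree.root.split
        assert (root_pos, root_group) in {(-6, "basic"), (8, "basic")}

    def test_leaf_names_follow_descending_size(self, two_motif_positives):
        tree = mdd_cluster(two_motif_positives, max_cluster_size=100)
        sizes = [leaf.size for leaf in tree.leaves]
        assert sizes == sorted(sizes, reverse=True)
        assert [leaf.name for leaf in tree.leaves] == [
            f"GSH{i}" for i in range(1, len(sizes) + 1)
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_raising_threshold_never_adds_leaves(self, seed, two_motif_positives):
        rng = np.random.default_rng(seed)
        frags = list(two_motif_positives)
        rng.shuffle(frags)
        frags = frags[:200]
        leaf_counts = [
            len(mdd_cluster(frags, threshold=t, max_cluster_size=50).leaves)
            for t in (20.0, 34.3, 60.0, 1e9)
        ]
        assert leaf_counts == sorted(leaf_counts, reverse=True)
        assert leaf_counts[-1] == 1  # infinite threshold -> single leaf

    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_leaves_partition_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        frags = [random_fragment(rng, n=3) for _ in range(rng.integers(5, 60))]
        tree = mdd_cluster(frags, threshold=10.0, max_cluster_size=5)
        members = [f for leaf in tree.leaves for f in leaf.fragments]
        assert sorted(id(f) for f in members) == sorted(id(f) for f in frags)

    def test_route_reaches_the_member_leaf(self, two_motif_positives):
        tree = mdd_cluster(two_motif_positives, max_cluster_size=100)
        for leaf in tree.leaves:
            for frag in leaf.fragments[:5]:
                assert tree.route(frag) is leaf


class TestLeafLogo:
    def test_identical_fragment_leaf_gives_one_hot_columns(self):
        frags = [make_fragment("K" + "A" * 4 + "C" + "A" * 5)] * 20
        tree = mdd_cluster(frags, max_cluster_size=5)
        pwm = leaf_logo(tree.leaves[0])
        assert ((pwm.matrix == 0) | (pwm.matrix == 1)).all()
        assert pwm.matrix.sum(axis=0) == pytest.approx(np.ones(11))

    def test_planted_motif_mass_at_its_position(self, two_motif_positives):
        tree = mdd_cluster(two_motif_positives, max_cluster_size=100)
        root_pos, root_group = tree.root.split
        has_leafs = [l for l in tree.leaves if (root_pos, root_group, "has") in l.path]
        grouping = AAGrouping.default()
        members = grouping.members(root_group)
        pwm = leaf_logo(has_leafs[0])
        col = 10 + root_pos
        mass = sum(pwm.matrix[AA_ORDER.index(aa), col] for aa in members)
        assert mass >= 0.8
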