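import numpy as np
import pytest

from conftest import make_fragment, random_fragments
from mddsite.alphabet import DEFAULT_SCHEME
from mddsite.mdd import (
    MddConfig,
    MddTree,
    group_contingency,
    mdd_partition,
    route,
    select_split,
)
from mddsite.synth import SynthConfig, MotifSpec, Subpopulation, generate_fragments


def brute_force_group_chi2(fragments, i, j, scheme=DEFAULT_SCHEME) -> float:
    """Independent double-loop grouped chi-square (X-excluded)."""
    g = scheme.groups
    obs = [[0] * 5 for _ in range(5)]
    for f in fragments:
        gi = scheme.group_of(f.residue_at(i))
        gj = scheme.group_of(f.residue_at(j))
        if gi is None or gj is None:
            continue
        obs[g.index(gi)][g.index(gj)] += 1
    total = sum(map(sum, obs))
    chi2 = 0.0
    for m in range(5):
        for c in range(5):
            e = sum(obs[m]) * sum(obs[r][c] for r in range(5)) / total
            if e > 0:
                chi2 += (obs[m][c] - e) ** 2 / e
    return chi2


class TestGroupContingency:
    def test_product_structure_gives_zero(self):
        """Groups at -1 and +1 in exact product proportions."""
        frags = []
        for a in "KD":        # basic / acidic at -1
            for b in "AF":    # hydrophobic / aromatic at +1
                frags += [make_fragment(a + "K" + b, center=2)] * 10
        assert group_contingency(frags, -1, 1).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_two_group_table(self):
        """20 (basic, basic) + 20 (acidic, acidic): 2x2 table [[20,0],[0,20]],
        expected 10 everywhere, chi2 = 4 * 100/10 = 40."""
        frags = [make_fragment("RKH", center=2)] * 20 + [make_fragment("DKE", center=2)] * 20
        assert group_contingency(frags, -1, 1).chi2 == pytest.approx(40.0)

    def test_x_fragments_excluded(self):
        frags = [make_fragment("RKH", center=2)] * 10 + [make_fragment("XKH", center=2)] * 3
        table = group_contingency(frags, -1, 1)
        assert table.n_excluded == 3
        assert table.total == 10

    def test_all_excluded_is_error(self):
        frags = [make_fragment("XKX", center=2)] * 5
        with pytest.raises(ValueError):
            group_contingency(frags, -1, 1)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            frags = random_fragments(rng, int(rng.integers(20, 100)), n=2)
            i, j = rng.choice([-2, -1, 1, 2], size=2, replace=False)
            assert group_contingency(frags, i, j).chi2 == pytest.approx(
                brute_force_group_chi2(frags, i, j), abs=1e-9
            )


def cooccurring_fragments(seed: int, size: int = 400):
    """Planted rule: basic at -8 in ~half the fragments, deterministically
    co-occurring with acidic at +3 (dependence driven from -8)."""
    rng = np.random.default_rng(seed)
    frags = []
    for f in random_fragments(rng, size, n=10):
        s = list(f.sequence)
        if rng.random() < 0.5:
            s[2] = "KRH"[rng.integers(3)]     # -8 basic
            s[13] = "DE"[rng.integers(2)]     # +3 acidic follows -8
        # other half keeps unconstrained background at both positions
        frags.append(make_fragment("".join(s)))
    return frags


class TestSelectSplit:
    def test_planted_cooccurrence_recovered(self):
        pos, group = select_split(cooccurring_fragments(seed=7))
        assert (pos, group) in {(-8, "basic"), (3, "acidic")}

    def test_independent_data_usually_no_split(self):
        """Under independence the max grouped chi2 over all pairs rarely
        clears the threshold when the window is small (few pairs tested)."""
        none_count = 0
        for seed in range(20):
            frags = random_fragments(np.random.default_rng(seed), 400, n=2)
            if select_split(frags) is None:
                none_count += 1
        assert none_count >= 16

    def test_two_fragments_returns_none(self):
        frags = [make_fragment("AKA", center=2), make_fragment("DKD", center=2)]
        assert select_split(frags) is None

    def test_deterministic(self):
        frags = cooccurring_fragments(seed=3)
        assert select_split(frags) == select_split(frags)


class TestMddPartition:
    def test_small_input_single_leaf(self, rng):
        frags = random_fragments(rng, 50, n=3)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
        assert tree.root.is_leaf
        assert tree.leaf_labels() == ["Glutar1"]

    def test_leaves_partition_members(self):
        frags = cooccurring_fragments(seed=1)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
        leaf_members = [i for leaf in tree.leaves for i in leaf.members]
        assert sorted(leaf_members) == list(range(len(frags)))
        for node in tree.internal_nodes:
            assert sorted(node.yes_child.members + node.no_child.members) == sorted(node.members)

    def test_routing_training_fragment_returns_containing_leaf(self):
        frags = cooccurring_fragments(seed=2)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
        by_label = {leaf.label: set(leaf.members) for leaf in tree.leaves}
        for idx in range(0, len(frags), 17):
            label = route(tree, frags[idx])
            assert idx in by_label[label]

    def test_depth_monotone_in_threshold(self):
        frags = cooccurring_fragments(seed=5)
        n_leaves = [
            len(mdd_partition(frags, MddConfig(chi2_threshold=t, max_cluster_size=50)).leaves)
            for t in (1e9, 34.3, 1.0)
        ]
        assert n_leaves[0] == 1
        assert n_leaves[0] <= n_leaves[1] <= n_leaves[2]

    def test_min_leaf_size_respected(self):
        frags = cooccurring_fragments(seed=6)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=50, min_leaf_size=30))
        assert all(leaf.size >= 30 for leaf in tree.leaves)

    def test_deterministic(self):
        frags = cooccurring_fragments(seed=4)
        t1 = mdd_partition(frags)
        t2 = mdd_partition(frags)
        assert t1.to_json() == t2.to_json()

    def test_preorder_yes_first_labelling(self):
        frags = cooccurring_fragments(seed=1)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
        if not tree.root.is_leaf:
            # first label lives under the yes branch
            node = tree.root.yes_child
            while not node.is_leaf:
                node = node.yes_child
            assert node.label == "Glutar1"


class TestRoute:
    def _tree(self):
        frags = cooccurring_fragments(seed=8)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
        assert not tree.root.is_leaf
        return tree

    def test_single_leaf_tree_routes_everything(self, rng):
        frags = random_fragments(rng, 20, n=10)
        tree = mdd_partition(frags, MddConfig(max_cluster_size=1000))
        assert {route(tree, f) for f in frags} == {"Glutar1"}

    def test_group_member_goes_yes(self):
        tree = self._tree()
        pos, group = tree.root.split_position, tree.root.split_group
        member = DEFAULT_SCHEME.members(group)[0]
        s = ["A"] * 21
        s[10] = "K"
        s[10 + pos] = member
        frag = make_fragment("".join(s))
        leaf = route(tree, frag)
        yes_labels = {l.label for l in tree.leaves
                      if set(l.members) <= set(tree.root.yes_child.members)}
        assert leaf in yes_labels

    def test_x_at_split_goes_no(self):
        tree = self._tree()
        pos = tree.root.split_position
        s = ["A"] * 21
        s[10] = "K"
        s[10 + pos] = "X"
        # X must be terminal-contiguous in real data, but routing only looks
        # at the split position; construct via left padding when possible
        frag = make_fragment("".join(s))
        no_labels = {l.label for l in tree.leaves
                     if set(l.members) <= set(tree.root.no_child.members)}
        assert route(tree, frag) in no_labels

    def test_window_mismatch_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            route(tree, make_fragment("AKA", center=2))


def test_tree_json_roundtrip():
    frags = cooccurring_fragments(seed=9)
    tree = mdd_partition(frags, MddConfig(max_cluster_size=100))
    clone = MddTree.from_json(tree.to_json())
    assert clone.to_json() == tree.to_json()
    for f in frags[::23]:
        assert route(clone, f) == route(tree, f)


def test_partition_recovers_single_planted_motif():
    """One dependent pair planted through a mixture: the first split finds
    one of its two (position, group) descriptions."""
    config = SynthConfig(
        n=10,
        subpopulations=(
            Subpopulation(200, (MotifSpec(-8, group="basic", penetrance=0.9),)),
            Subpopulation(200, (MotifSpec(4, group="acidic", penetrance=0.9),)),
            Subpopulation(100, ()),
        ),
        seed=11,
    )
    positives, _ = generate_fragments(config)
    tree = mdd_partition(positives, MddConfig())
    assert tree.splits[0] in {(-8, "basic"), (4, "acidic")}
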