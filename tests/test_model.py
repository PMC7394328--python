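import numpy as np
import pytest

from conftest import make_fragment, random_fragments
from mddsite.mdd import MddConfig, mdd_partition
from mddsite.model import (
    SMALL_C_GRID,
    SMALL_GAMMA_GRID,
    IntegratedModel,
    SvmConfig,
    allocate_negatives,
    build_meta_vectors,
    fit_svm,
    grid_search,
    train_integrated,
    train_subgroup_models,
)
from mddsite.synth import (
    MotifSpec,
    Subpopulation,
    SynthConfig,
    generate_fragments,
    two_motif_config,
)

FAST_SVM = SvmConfig(c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, cv_folds=3)


def separable_fragments():
    """Positives carry D-rich flanks, negatives V-rich: linearly separable
    in AAC space."""
    pos = [make_fragment("D" * 10 + "K" + "D" * 10, f"p{i}", label="positive")
           for i in range(20)]
    neg = [make_fragment("V" * 10 + "K" + "V" * 10, f"n{i}", label="negative")
           for i in range(20)]
    return pos, neg


def noisy_separable(seed=0, count=40):
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for i, f in enumerate(random_fragments(rng, count)):
        s = list(f.sequence)
        for j in rng.choice(20, size=8, replace=False):
            s[j if j < 10 else j + 1] = "D"
        pos.append(make_fragment("".join(s), f"p{i}", label="positive"))
    for i, f in enumerate(random_fragments(rng, count)):
        neg.append(make_fragment(f.sequence, f"n{i}", label="negative"))
    return pos, neg


class TestGridSearch:
    def test_separable_reaches_perfect_cv(self):
        pos, neg = separable_fragments()
        from mddsite.encoding import encode_matrix

        X = encode_matrix(pos + neg, "aac")
        y = np.array([1] * 20 + [0] * 20)
        _, _, score = grid_search(X, y, k=3, c_grid=SMALL_C_GRID,
                                  gamma_grid=SMALL_GAMMA_GRID, seed=0)
        assert score == 1.0

    def test_null_labels_score_near_chance(self, rng):
        X = rng.normal(size=(120, 5))
        y = np.array([1] * 40 + [0] * 80)  # majority class 2/3
        _, _, score = grid_search(X, y, k=3, c_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        assert abs(score - 2 / 3) < 0.1

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 30 + [0] * 30)
        a = grid_search(X, y, k=3, c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, seed=9)
        b = grid_search(X, y, k=3, c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, seed=9)
        assert a == b

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            grid_search(X, np.ones(10), k=2)


class TestSubgroupModels:
    def test_single_leaf_tree_equals_global_model(self):
        pos, neg = noisy_separable(seed=1)
        tree = mdd_partition(pos, MddConfig(max_cluster_size=10_000))
        assert len(tree.leaves) == 1
        models = train_subgroup_models(tree, pos, neg, svm_config=FAST_SVM, seed=0,
                                       negative_ratio=None)
        global_model = fit_svm(pos, neg, svm_config=FAST_SVM, seed=0)
        probe = random_fragments(np.random.default_rng(5), 10)
        assert np.allclose(models[0].predict_proba(probe), global_model.predict_proba(probe))

    def test_tiny_leaf_raises_helpful_error(self):
        pos, neg = separable_fragments()
        tree = mdd_partition(pos[:1], MddConfig(max_cluster_size=10_000))
        with pytest.raises(ValueError, match="min_leaf_size"):
            train_subgroup_models(tree, pos[:1], neg, svm_config=FAST_SVM, seed=0)

    def test_negative_allocation_ratio(self):
        cfg = two_motif_config(seed=3, n_subpop=100, n_background=50, n_negatives=600)
        pos, neg = generate_fragments(cfg)
        tree = mdd_partition(pos, MddConfig(max_cluster_size=100))
        alloc = allocate_negatives(tree, neg, ratio=2.0, seed=0)
        seen = set()
        for leaf in tree.leaves:
            share = alloc[leaf.label]
            assert len(share) == round(2.0 * leaf.size)
            keys = {id(f) for f in share}
            assert not keys & seen  # disjoint shares
            seen |= keys
        routed = allocate_negatives(tree, neg, ratio=None, seed=0, method="routed")
        assert sum(len(v) for v in routed.values()) == len(neg)
        for leaf in tree.leaves:
            from mddsite.mdd import route
            assert all(route(tree, f) == leaf.label for f in routed[leaf.label])


class TestMetaVectors:
    def _setup(self):
        pos, neg = noisy_separable(seed=2)
        tree = mdd_partition(pos, MddConfig(max_cluster_size=10_000))
        models = train_subgroup_models(tree, pos, neg, svm_config=FAST_SVM, seed=0,
                                       negative_ratio=None)
        return pos, neg, models

    def test_shape_and_range(self):
        pos, neg, models = self._setup()
        M = build_meta_vectors(models, pos + neg)
        assert M.shape == (len(pos) + len(neg), len(models))
        assert ((M >= 0) & (M <= 1)).all()

    def test_out_of_fold_differs_in_sample(self):
        pos, neg, models = self._setup()
        in_sample = build_meta_vectors(models, pos + neg, out_of_fold=False)
        oof = build_meta_vectors(models, pos + neg, out_of_fold=True, k=3)
        assert not np.allclose(in_sample, oof)
        # fragments outside every training set are unaffected
        probe = random_fragments(np.random.default_rng(77), 5)
        assert np.allclose(
            build_meta_vectors(models, probe, out_of_fold=True, k=3),
            build_meta_vectors(models, probe, out_of_fold=False),
        )


class TestIntegratedModel:
    def _train(self, seed=0):
        cfg = two_motif_config(seed=seed, n_subpop=60, n_background=30, n_negatives=300)
        pos, neg = generate_fragments(cfg)
        model = train_integrated(
            pos, neg, svm_config=FAST_SVM,
            mdd_config=MddConfig(max_cluster_size=100), seed=seed, oof_k=3,
        )
        return model, pos, neg

    def test_probabilities_and_labels_consistent(self):
        model, pos, neg = self._train()
        preds = model.predict(pos[:20] + neg[:20])
        for p in preds:
            assert 0 <= p.probability <= 1
            assert p.label == (p.probability >= model.threshold)
            assert p.motif in model.tree.leaf_labels()

    def test_training_reproducible(self):
        model_a, pos, neg = self._train(seed=4)
        model_b, _, _ = self._train(seed=4)
        probe = random_fragments(np.random.default_rng(1), 25)
        assert np.array_equal(model_a.predict_proba(probe), model_b.predict_proba(probe))

    def test_separable_training_accuracy_is_one(self):
        pos, neg = separable_fragments()
        model = train_integrated(pos, neg, svm_config=FAST_SVM,
                                 mdd_config=MddConfig(max_cluster_size=10_000),
                                 seed=0, oof_k=2, negative_ratio=None)
        probs = model.predict_proba(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        assert ((probs >= 0.5).astype(int) == y).all()

    def test_empty_negatives_rejected(self):
        pos, _ = separable_fragments()
        with pytest.raises(ValueError):
            train_integrated(pos, [], svm_config=FAST_SVM, seed=0)

    def test_window_mismatch_rejected(self):
        model, _, _ = self._train()
        with pytest.raises(ValueError):
            model.predict_proba([make_fragment("AKA", center=2)])

    def test_save_load_roundtrip(self, tmp_path):
        model, pos, neg = self._train()
        model.save(tmp_path / "bundle")
        clone = IntegratedModel.load(tmp_path / "bundle")
        probe = pos[:10] + neg[:10]
        assert np.array_equal(model.predict_proba(probe), clone.predict_proba(probe))
        assert [m.label for m in clone.subgroup_models] == [
            m.label for m in model.subgroup_models
        ]


def test_predict_sites_shape_over_protein():
    """End-to-end shape check: a protein FASTA in, one row per lysine out."""
    from mddsite.seqio import ProteinRecord, extract_fragment

    pos, neg = noisy_separable(seed=3)
    model = train_integrated(pos, neg, svm_config=FAST_SVM,
                             mdd_config=MddConfig(max_cluster_size=10_000), seed=0, oof_k=3)
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    protein = ProteinRecord("query", seq)
    k_sites = [i + 1 for i, c in enumerate(seq) if c == "K"]
    frags = [extract_fragment(protein, c, 10) for c in k_sites]
    preds = model.predict(frags)
    assert len(preds) == len(k_sites)
    assert [p.fragment.center for p in preds] == k_sites
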