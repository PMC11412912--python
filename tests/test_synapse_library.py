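import numpy as np
import pandas as pd
import pytest

from synprot.synapse_library import (
    AnnotationSets,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    _coverage,
    assemble_library,
    build_training_set,
    estimate_library_fdr,
    extract_features,
    isoelectric_point,
    roc_curve_auc,
    train_and_classify,
)
from synprot.synthetic_data import (
    FEATURE_COLUMNS,
    simulate_classifier_proteome,
)


def _ann(**kw):
    defaults = dict(broad_postsynaptic=frozenset(),
                    curated_presynaptic=frozenset(),
                    curated_postsynaptic=frozenset(),
                    nonsynaptic_membrane=frozenset(),
                    cytosolic_er=frozenset())
    defaults.update({k: frozenset(v) for k, v in kw.items()})
    return AnnotationSets(**defaults)


class TestBuildTrainingSet:
    def test_dual_annotated_gene_is_postsynaptic(self):
        ann = _ann(broad_postsynaptic={"X"}, curated_presynaptic={"A"},
                   curated_postsynaptic={"A"})
        out = build_training_set(ann).set_index("gene")
        assert out.loc["A", "label"] == POSITIVE_LABEL

    def test_exclusive_presynaptic_removed_from_broad_set(self):
        ann = _ann(broad_postsynaptic={"A", "B"},
                   curated_presynaptic={"A"}, curated_postsynaptic={"C"})
        out = build_training_set(ann).set_index("gene")
        assert out.loc["A", "label"] == NEGATIVE_LABEL
        assert out.loc["B", "label"] == POSITIVE_LABEL
        assert out.loc["C", "label"] == POSITIVE_LABEL

    def test_disjoint_toy_sets_positive_size(self):
        broad = {f"b{i}" for i in range(5)}
        pre = {f"p{i}" for i in range(3)}
        post = {f"q{i}" for i in range(4)}
        ann = _ann(broad_postsynaptic=broad, curated_presynaptic=pre,
                   curated_postsynaptic=post)
        out = build_training_set(ann)
        assert (out["label"] == POSITIVE_LABEL).sum() == len(broad | post)

    def test_matches_set_algebra_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        pick = lambda: {g for g in genes if rng.random() < 0.3}  # noqa: E731
        for _ in range(20):
            broad, pre, post, mem, cyt = (pick() for _ in range(5))
            if not (broad | post):
                continue
            ann = _ann(broad_postsynaptic=broad, curated_presynaptic=pre,
                       curated_postsynaptic=post,
                       nonsynaptic_membrane=mem, cytosolic_er=cyt)
            out = build_training_set(ann)
            positives = set(out.loc[out["label"] == POSITIVE_LABEL, "gene"])
            expected_pos = (broad - (pre - post)) | post
            assert positives == expected_pos
            negatives = set(out.loc[out["label"] == NEGATIVE_LABEL, "gene"])
            assert negatives == ((pre - post) | mem | cyt) - expected_pos

    def test_order_invariance(self):
        ann = _ann(broad_postsynaptic={"B", "A", "C"},
                   curated_presynaptic={"C"}, curated_postsynaptic={"D"})
        a = build_training_set(ann)
        b = build_training_set(ann)
        pd.testing.assert_frame_equal(a, b)

    def test_namespace_mismatch_with_universe_raises(self):
        ann = _ann(broad_postsynaptic={"A"}, curated_postsynaptic={"B"})
        with pytest.raises(ValueError, match="namespace"):
            build_training_set(ann, universe={"ENSMUSG000001"})


class TestFeatureExtraction:
    def _peptides(self, rows, channels=("pre", "cyto", "post")):
        recs = []
        for pep, prot, spec, vals in rows:
            rec = {"peptide": pep, "protein": prot, "is_phospho": False,
                   "spec_count": spec}
            rec.update(dict(zip(channels, vals)))
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_coverage_interval_union(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), 100))
        assert _coverage(seq, [seq[0:30], seq[20:50]]) == pytest.approx(0.5)

    def test_single_peptide_protein_excluded(self, rng):
        seq = "".join(rng.choice(list("ACDEFG"), 50))
        peps = self._peptides([
            (seq[:10], "P1", 3, (1.0, 1.0, 1.0)),
            (seq[:10], "P2", 3, (1.0, 1.0, 1.0)),
            (seq[12:22], "P2", 2, (2.0, 2.0, 2.0)),
        ])
        out = extract_features(
            peps, {"pre": "pre", "cyto": "cyto", "post": "post"},
            {"P1": seq, "P2": seq})
        assert list(out["protein"]) == ["P2"]

    def test_fold_feature_ratio(self, rng):
        seq = "".join(rng.choice(list("ACDEFG"), 40))
        peps = self._peptides([
            (seq[:10], "P1", 1, (1.0, 10.0, 20.0)),
            (seq[11:21], "P1", 1, (1.0, 10.0, 20.0)),
        ])
        out = extract_features(
            peps, {"pre": "pre", "cyto": "cyto", "post": "post"},
            {"P1": seq})
        assert out["fold_post_over_cyto"].iloc[0] == pytest.approx(2.0)
        assert out["spec_count"].iloc[0] == 2

    def test_missing_sequence_listed(self, rng):
        seq = "ACDEFGHIKLMNPQRS"
        peps = self._peptides([("ACDEF", "P9", 1, (1, 1, 1)),
                               ("GHIKL", "P9", 1, (1, 1, 1))])
        with pytest.raises(ValueError, match="P9"):
            extract_features(
                peps, {"pre": "pre", "cyto": "cyto", "post": "post"}, {})

    def test_pi_orders_acidic_below_basic(self):
        assert isoelectric_point("DDDDDDG") < 5
        assert isoelectric_point("KKKKKKG") > 9


class TestClassifier:
    def test_unlabeled_duplicates_get_identical_scores(self):
        X, truth = simulate_classifier_proteome(20, 2.0, seed=3)
        X = X[FEATURE_COLUMNS]
        labels = truth.true_class.map(
            lambda c: POSITIVE_LABEL if c == "postsynaptic"
            else NEGATIVE_LABEL)
        dup = X.iloc[:2].copy()
        dup.index = ["dup_a", "dup_b"]
        dup.iloc[1] = dup.iloc[0]
        X2 = pd.concat([X, dup])
        scores = train_and_classify(X2, labels, n_estimators=50, seed=0)
        assert scores["dup_a"] == scores["dup_b"]

    def test_deterministic_under_fixed_seed(self):
        X, truth = simulate_classifier_proteome(20, 2.0, seed=3)
        labels = truth.true_class.map(
            lambda c: POSITIVE_LABEL if c == "postsynaptic"
            else NEGATIVE_LABEL)
        s1 = train_and_classify(X[FEATURE_COLUMNS], labels,
                                n_estimators=50, seed=4)
        s2 = train_and_classify(X[FEATURE_COLUMNS], labels,
                                n_estimators=50, seed=4)
        pd.testing.assert_series_equal(s1, s2)

    def test_single_class_labels_rejected(self):
        X, _ = simulate_classifier_proteome(10, 1.0, seed=1)
        labels = pd.Series(POSITIVE_LABEL, index=X.index)
        with pytest.raises(ValueError):
            train_and_classify(X[FEATURE_COLUMNS], labels)


class TestRocCurve:
    def test_perfect_separation(self):
        *_, auroc = roc_curve_auc([0.1, 0.2, 0.8, 0.9],
                                  [False, False, True, True])
        assert auroc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.uniform(0, 1, 4000)
        labels = rng.random(4000) < 0.5
        *_, auroc = roc_curve_auc(scores, labels)
        assert auroc == pytest.approx(0.5, abs=0.03)

    def test_matches_pairwise_concordance_oracle(self, rng):
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=30)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        *_, auroc = roc_curve_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.9], [True, True])


class TestLibraryAssembly:
    def test_two_experiment_rule(self):
        scores = pd.DataFrame(
            {"e1": [0.9, 0.9, 0.2], "e2": [0.8, 0.3, 0.3],
             "e3": [0.2, 0.1, 0.9]},
            index=["g1", "g2", "g3"])
        lib = assemble_library(scores)
        assert bool(lib.loc["g1", "included"])
        assert not lib.loc["g2", "included"]  # positive in only 1 of 3
        assert not lib.loc["g3", "included"]

    def test_positive_in_two_of_two_included(self):
        scores = pd.DataFrame({"e1": [0.6], "e2": [0.7]}, index=["g"])
        assert bool(assemble_library(scores).loc["g", "included"])

    def test_matches_count_and_filter_oracle(self, rng):
        scores = pd.DataFrame(rng.uniform(0, 1, (50, 4)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        lib = assemble_library(scores, threshold=0.6)
        for g in scores.index:
            n = int((scores.loc[g] >= 0.6).sum())
            assert lib.loc[g, "n_experiments_positive"] == n
            assert lib.loc[g, "included"] == (n >= 2)

    def test_fewer_than_two_experiments_rejected(self):
        with pytest.raises(ValueError):
            assemble_library(pd.DataFrame({"e1": [0.9]}, index=["g"]))


class TestLibraryFdr:
    def test_clean_library_zero_fdr(self):
        lib = pd.DataFrame({"included": [True] * 5},
                           index=[f"g{i}" for i in range(5)])
        out = estimate_library_fdr(lib, _ann(broad_postsynaptic={"x"}))
        assert out == {"fdr_nonsynaptic_membrane": 0.0,
                       "fdr_presynaptic": 0.0}

    def test_forced_ratio(self):
        genes = [f"g{i}" for i in range(100)]
        lib = pd.DataFrame({"included": [True] * 100}, index=genes)
        ann = _ann(broad_postsynaptic={"x"},
                   curated_presynaptic={"g0", "g1"})
        out = estimate_library_fdr(lib, ann)
        assert out["fdr_presynaptic"] == pytest.approx(0.02)

    def test_bounds_and_count_consistency(self, rng):
        genes = [f"g{i}" for i in range(60)]
        lib = pd.DataFrame({"included": rng.random(60) < 0.7}, index=genes)
        ann = _ann(broad_postsynaptic={"x"},
                   curated_presynaptic=set(rng.choice(genes, 10)),
                   nonsynaptic_membrane=set(rng.choice(genes, 10)))
        out = estimate_library_fdr(lib, ann)
        n = int(lib["included"].sum())
        for v in out.values():
            assert 0.0 <= v <= 1.0
        total_contaminants = sum(round(v * n) for v in out.values())
        assert total_contaminants <= n

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            estimate_library_fdr(pd.DataFrame(), _ann())


def test_classifier_fdr_tracks_ground_truth_contamination():
    """An assembled library's annotation-based FDR estimate should sit
    near the truth-derived contaminant fraction on synthetic data."""
    X, truth = simulate_classifier_proteome(100, 3.0, seed=8)
    labels = truth.true_class.map(
        lambda c: POSITIVE_LABEL if c == "postsynaptic" else NEGATIVE_LABEL)
    scores = {}
    for i, seed in enumerate((11, 12)):
        scores[f"e{i}"] = train_and_classify(
            X[FEATURE_COLUMNS], labels, n_estimators=100, seed=seed)
    lib = assemble_library(pd.DataFrame(scores), threshold=0.5)
    ann = _ann(
        broad_postsynaptic=set(
            truth.true_class.index[truth.true_class == "postsynaptic"]),
        curated_presynaptic=set(
            truth.true_class.index[truth.true_class == "presynaptic"]),
        nonsynaptic_membrane=set(
            truth.true_class.index[
                truth.true_class == "nonsynaptic_membrane"]),
    )
    est = estimate_library_fdr(lib, ann)
    included = lib.index[lib["included"]]
    true_contaminant = float(
        (truth.true_class.loc[included] != "postsynaptic").mean())
    reported = est["fdr_presynaptic"] + est["fdr_nonsynaptic_membrane"]
    assert reported <= true_contaminant + 1e-12
    if true_contaminant > 0:
        assert reported >= 0.5 * true_contaminant - 0.05
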