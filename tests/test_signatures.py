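import numpy as np
import pytest

from nucloc.features import FeatureVector
from nucloc.plsi import PLSIModel
from nucloc.signatures import (
    BASIC_POLAR_HYDROPHOBIC_GROUPS,
    NON_NUCLEAR,
    NUCLEAR,
    PHYSICOCHEMICAL_GROUPS,
    SignatureEntry,
    SignatureSet,
    composition_profile,
    compute_topic_preferences,
    load_reference_signatures,
    load_signature_tsv,
    reduce_to_signatures,
    select_signatures,
    signature_vector,
    write_signature_tsv,
)


def make_model(p_wt, p_td, docs, vocab):
    p_wt = np.asarray(p_wt, dtype=float)
    p_td = np.asarray(p_td, dtype=float)
    return PLSIModel(
        K=p_td.shape[0],
        documents=docs,
        vocabulary=vocab,
        word_given_topic=p_wt,
        topic_given_doc=p_td,
        doc_prior=np.full(len(docs), 1 / len(docs)),
    )


LABELS4 = {"n1": NUCLEAR, "n2": NUCLEAR, "c1": NON_NUCLEAR, "c2": NON_NUCLEAR}


class TestTopicPreferences:
    def test_extreme_separation(self):
        p_td = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        model = make_model(np.full((2, 2), 0.5), p_td, ["n1", "n2", "c1", "c2"], ["K1K", "L2L"])
        prefs = compute_topic_preferences(model, LABELS4)
        assert prefs[0].confidence == pytest.approx(1.0)
        assert prefs[0].preferred_class == NUCLEAR
        assert prefs[1].preferred_class == NON_NUCLEAR

    def test_uniform_no_signal(self):
        model = make_model(np.full((2, 4), 0.25), np.full((4, 4), 0.25), ["n1", "n2", "c1", "c2"], ["K1K", "L2L"])
        for p in compute_topic_preferences(model, LABELS4):
            assert p.confidence == pytest.approx(0.0)

    def test_hand_computed_means(self):
        p_td = np.array([[0.8, 0.6, 0.3, 0.1], [0.2, 0.4, 0.7, 0.9]])
        model = make_model(np.full((2, 2), 0.5), p_td, ["n1", "n2", "c1", "c2"], ["K1K", "L2L"])
        prefs = compute_topic_preferences(model, LABELS4)
        assert prefs[0].mean_weight_nuclear == pytest.approx(0.7)
        assert prefs[0].mean_weight_non_nuclear == pytest.approx(0.2)
        assert prefs[1].mean_weight_nuclear == pytest.approx(0.3)
        assert prefs[1].confidence == pytest.approx(0.5)

    def test_missing_class_error(self):
        model = make_model(np.full((2, 2), 0.5), np.full((2, 2), 0.5), ["n1", "n2"], ["K1K", "L2L"])
        with pytest.raises(ValueError, match="non_nuclear"):
            compute_topic_preferences(model, {"n1": NUCLEAR, "n2": NUCLEAR})


class TestSelection:
    def test_minimal_selection(self):
        vocab = ["K1K", "R2R", "L2L", "I3I"]
        p_wt = np.array([[0.5, 0.05], [0.3, 0.05], [0.1, 0.6], [0.1, 0.3]])
        p_td = np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.9, 0.9]])
        model = make_model(p_wt, p_td, ["n1", "n2", "c1", "c2"], vocab)
        prefs = compute_topic_preferences(model, LABELS4)
        sigs = select_signatures(model, prefs, topics_per_class=1, words_per_topic=1)
        assert sigs.words == ["K1K", "L2L"]
        assert [e.class_label for e in sigs.entries] == [NUCLEAR, NON_NUCLEAR]

    def test_sorting_oracle(self):
        rng = np.random.default_rng(0)
        vocab = [f"A{d}A" for d in range(12)]
        p_wt = rng.dirichlet(np.ones(12), size=2).T
        p_td = np.array([[0.9, 0.8, 0.2, 0.3], [0.1, 0.2, 0.8, 0.7]])
        model = make_model(p_wt, p_td, ["n1", "n2", "c1", "c2"], vocab)
        prefs = compute_topic_preferences(model, LABELS4)
        sigs = select_signatures(model, prefs, topics_per_class=1, words_per_topic=4)
        expect_nuc = [vocab[j] for j in np.argsort(-p_wt[:, 0], kind="stable")[:4]]
        assert [e.word for e in sigs.for_class(NUCLEAR)] == expect_nuc

    def test_size_bound(self):
        rng = np.random.default_rng(5)
        vocab = [f"K{d}K" for d in range(14)] + [f"L{d}L" for d in range(14)]
        p_wt = rng.dirichlet(np.ones(28), size=4).T
        p_td = rng.dirichlet(np.ones(4), size=6).T
        docs = [f"n{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
        labels = {d: (NUCLEAR if d.startswith("n") else NON_NUCLEAR) for d in docs}
        model = make_model(p_wt, p_td, docs, vocab)
        prefs = compute_topic_preferences(model, labels)
        sigs = select_signatures(model, prefs, topics_per_class=2, words_per_topic=5)
        assert len(sigs) <= 2 * 2 * 5
        assert len(set(sigs.words)) == len(sigs.words)

    def test_fewer_topics_than_requested_warns(self):
        p_td = np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.9, 0.9]])
        model = make_model(np.full((2, 2), 0.5), p_td, ["n1", "n2", "c1", "c2"], ["K1K", "L2L"])
        prefs = compute_topic_preferences(model, LABELS4)
        with pytest.warns(UserWarning, match="taking all"):
            select_signatures(model, prefs, topics_per_class=5, words_per_topic=1)


class TestReduction:
    SIGS = SignatureSet(
        (
            SignatureEntry("K2K", NUCLEAR, 0, 1, 0.5),
            SignatureEntry("R0R", NUCLEAR, 0, 2, 0.3),
            SignatureEntry("L2L", NON_NUCLEAR, 1, 1, 0.6),
        )
    )

    def test_projection(self):
        fv = FeatureVector("p", {"K2K": 0.7, "A0A": 0.2}, d_max=2)
        reduced = reduce_to_signatures(fv, self.SIGS)
        assert reduced.weights == {"K2K": 0.7, "R0R": 0.0, "L2L": 0.0}
        np.testing.assert_array_equal(signature_vector(fv, self.SIGS), [0.7, 0.0, 0.0])

    def test_disjoint_gives_zero_vector(self):
        fv = FeatureVector("p", {"A0A": 0.9}, d_max=2)
        vec = signature_vector(fv, self.SIGS)
        assert vec.shape == (3,)
        assert not vec.any()

    def test_empty_signature_set_rejected(self):
        with pytest.raises(ValueError):
            reduce_to_signatures(FeatureVector("p", {}, 1), SignatureSet(()))

    def test_duplicate_words_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SignatureSet(
                (
                    SignatureEntry("K2K", NUCLEAR, 0, 1, 0.5),
                    SignatureEntry("K2K", NON_NUCLEAR, 1, 1, 0.5),
                )
            )


class TestComposition:
    def test_forced_composition(self):
        sigs = SignatureSet(
            (
                SignatureEntry("K1K", NUCLEAR, 0, 1, 0.5),
                SignatureEntry("R2R", NUCLEAR, 0, 2, 0.5),
            )
        )
        comp = composition_profile(sigs)
        assert comp[NUCLEAR] == {"K": 0.5, "R": 0.5}
        grouped = composition_profile(sigs, grouping="physicochemical")
        assert grouped[NUCLEAR] == {"charged": 1.0}

    def test_groups_partition_standard_letters(self):
        for scheme in (PHYSICOCHEMICAL_GROUPS, BASIC_POLAR_HYDROPHOBIC_GROUPS):
            letters = "".join(scheme.values())
            assert sorted(letters) == sorted("ACDEFGHIKLMNPQRSTVWY")
        assert sorted(len(v) for v in PHYSICOCHEMICAL_GROUPS.values()) == [3, 5, 6, 6]

    def test_frequencies_sum_to_one(self):
        sigs = load_reference_signatures()
        for grouping in ("none", "physicochemical"):
            comp = composition_profile(sigs, grouping)
            for cls in (NUCLEAR, NON_NUCLEAR):
                assert sum(comp[cls].values()) == pytest.approx(1.0, abs=1e-9)

    def test_reference_nuclear_prefers_basic_residues(self):
        # nuclear signature letters are far richer in R/H/K than non-nuclear ones
        comp = composition_profile(load_reference_signatures())
        basic = lambda c: sum(comp[c].get(a, 0.0) for a in "RHK")
        assert basic(NUCLEAR) > basic(NON_NUCLEAR)


class TestReferenceList:
    def test_total_count(self):
        sigs = load_reference_signatures()
        assert len(sigs) == 366
        assert len(sigs.for_class(NUCLEAR)) == 183
        assert len(sigs.for_class(NON_NUCLEAR)) == 183

    def test_tsv_roundtrip(self, tmp_path):
        sigs = load_reference_signatures()
        path = tmp_path / "sigs.tsv"
        write_signature_tsv(sigs, path)
        back = load_signature_tsv(path)
        assert back.words == sigs.words
        assert [e.class_label for e in back.entries] == [e.class_label for e in sigs.entries]
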