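"""Response labelling, cluster identification, and topic aggregation,
checked against worked examples and exhaustive brute-force oracles."""

import numpy as np
import pytest

from vflda import (ClusterConfig, Lexicon, ScoredResponse, Transcript,
                   cluster_threshold, error_topic_correlation,
                   identify_clusters, normalize_word, score_transcript,
                   summed_topic_probabilities, within_cluster_error_share)
from vflda.scoring import CORRECT, INTRUSION, NONWORD, PERSEVERATION


# --- normalization -----------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    ("Tiger ", "tiger"),
    ("rose bed", "rose_bed"),
    ("SJØLØVE", "sjøløve"),
    ("guinea-pig!", "guineapig"),
    ("", None),
    ("  ...  ", None),
])
def test_normalize_word(raw, expected):
    assert normalize_word(raw) == expected


# --- transcript scoring ------------------------------------------------

def _transcript(words, group="ad"):
    return Transcript("s", group, [(w, 1.0 + 2.0 * i) for i, w in enumerate(words)])


def test_worked_five_word_example(make_profile):
    """tiger, car, elephant, lion, tiger -> 1 intrusion (car, a profiled
    real word outside the category) and 1 perseveration (second tiger)."""
    lexicon = Lexicon(frozenset({"tiger", "elephant", "lion", "cow"}))
    profiles = {"car": make_profile({0: 0.9})}
    scored = score_transcript(_transcript(
        ["tiger", "car", "elephant", "lion", "tiger"]), lexicon, profiles)
    labels = [r.label for r in scored]
    assert labels == [CORRECT, INTRUSION, CORRECT, CORRECT, PERSEVERATION]
    assert scored[4].first_occurrence_index == 0


def test_empty_transcript_scores_empty(animals_lexicon):
    assert score_transcript(_transcript([]), animals_lexicon, {}) == []


def test_unordered_onsets_rejected(animals_lexicon):
    t = Transcript.__new__(Transcript)
    t.subject_id, t.group, t.duration = "s", "g", 60.0
    t.responses = [("cow", 5.0), ("pig", 3.0)]
    with pytest.raises(ValueError, match="increasing"):
        score_transcript(t, animals_lexicon, {})


def test_unprofiled_noncategory_word_is_nonword_and_repeat_of_intrusion_perseverates(make_profile):
    lexicon = Lexicon(frozenset({"lion"}))
    profiles = {"car": make_profile({1: 0.8})}
    scored = score_transcript(
        _transcript(["kemse", "car", "car", "lion", "lion"]), lexicon, profiles)
    assert [r.label for r in scored] == [
        NONWORD, INTRUSION, PERSEVERATION, CORRECT, PERSEVERATION]
    assert scored[0].profile is None


def test_multiword_intrusion_profile_falls_back_to_token_mean(make_profile):
    lexicon = Lexicon(frozenset({"lion"}))
    profiles = {"rose": make_profile({2: 0.6}), "bed": make_profile({3: 0.6})}
    scored = score_transcript(_transcript(["rose bed"]), lexicon, profiles)
    assert scored[0].label == INTRUSION
    expected = (profiles["rose"] + profiles["bed"]) / 2
    np.testing.assert_allclose(scored[0].profile, expected / expected.sum())


def test_random_sequences_match_brute_force_label_oracle(animals_lexicon):
    """First-occurrence/membership counting oracle over 500 random draws."""
    rng = np.random.default_rng(42)
    vocab = ["cow", "pig", "lion", "car", "boat", "kemse"]
    profiled = {"car", "boat"}
    profiles = {w: np.array([1.0]) for w in profiled}
    for _ in range(500):
        words = rng.choice(vocab, size=rng.integers(0, 12)).tolist()
        scored = score_transcript(_transcript(words), animals_lexicon, profiles)
        seen = set()
        expected = []
        for w in words:
            if w in seen:
                expected.append(PERSEVERATION)
            else:
                seen.add(w)
                if w in animals_lexicon:
                    expected.append(CORRECT)
                elif w in profiled:
                    expected.append(INTRUSION)
                else:
                    expected.append(NONWORD)
        assert [r.label for r in scored] == expected
        assert len(scored) == len(words)  # label conservation


# --- cluster threshold and identification ------------------------------

@pytest.mark.parametrize("K,expected", [(14, 1 / 14 * 0.5), (2, 0.25), (10, 0.05)])
def test_cluster_threshold(K, expected):
    assert cluster_threshold(K) == pytest.approx(expected, abs=1e-15)


def test_cluster_threshold_rejects_nonpositive_K():
    with pytest.raises(ValueError):
        cluster_threshold(0)


def _scored_from_profiles(profiles):
    return [ScoredResponse(i, f"w{i}", float(i), CORRECT, i, p)
            for i, p in enumerate(profiles)]


def test_worked_cluster_example_with_transposition(make_profile):
    """monkey(3), gorilla(3), chimpanzee(3,9), kangaroo(8,9): one 4-response
    cluster; the linking topic transposes from 3 to 9 at chimpanzee."""
    profiles = [make_profile({3: 0.9}), make_profile({3: 0.9}),
                make_profile({3: 0.45, 9: 0.45}),
                make_profile({8: 0.5, 9: 0.4})]
    spans = identify_clusters(_scored_from_profiles(profiles), ClusterConfig(K=14))
    assert len(spans) == 1
    assert spans[0].member_indices == [0, 1, 2, 3]
    assert spans[0].size == 4
    assert len(spans[0].transpositions) == 1
    tr = spans[0].transpositions[0]
    assert tr.position == 2            # chimpanzee
    assert tr.from_topics == {3}
    assert tr.to_topics == {9}


def test_pairwise_disjoint_profiles_form_no_clusters(make_profile):
    profiles = [make_profile({k: 0.9}) for k in range(5)]
    assert identify_clusters(_scored_from_profiles(profiles),
                             ClusterConfig(K=14)) == []


def test_no_profile_responses_never_link(make_profile):
    profiles = [make_profile({2: 0.9}), None, make_profile({2: 0.9})]
    assert identify_clusters(_scored_from_profiles(profiles),
                             ClusterConfig(K=14)) == []


def test_profile_length_mismatch_rejected(make_profile):
    scored = _scored_from_profiles([make_profile({1: 0.9}, K=10)])
    with pytest.raises(ValueError, match="K"):
        identify_clusters(scored, ClusterConfig(K=14))


def _brute_force_spans(profiles, c):
    """Exhaustive oracle: test every adjacent pair, then assemble maximal
    runs of linked pairs."""
    n = len(profiles)
    linked = []
    for i in range(n - 1):
        a, b = profiles[i], profiles[i + 1]
        linked.append(a is not None and b is not None
                      and any(a[k] > c and b[k] > c for k in range(len(a))))
    spans, i = [], 0
    while i < n - 1:
        if linked[i]:
            j = i
            while j < n - 1 and linked[j]:
                j += 1
            spans.append(list(range(i, j + 1)))
            i = j + 1
        else:
            i += 1
    return spans


def test_cluster_identification_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    K = 6
    cfg = ClusterConfig(K=K)
    for _ in range(1000):
        n = int(rng.integers(0, 13))
        profiles = []
        for _ in range(n):
            if rng.random() < 0.1:
                profiles.append(None)
            else:
                p = rng.dirichlet(np.full(K, 0.4))
                profiles.append(p)
        spans = identify_clusters(_scored_from_profiles(profiles), cfg)
        assert [s.member_indices for s in spans] == _brute_force_spans(
            profiles, cfg.threshold)


def test_raising_threshold_never_adds_linked_pairs():
    rng = np.random.default_rng(11)
    K = 6
    profiles = [rng.dirichlet(np.full(K, 0.4)) for _ in range(30)]
    scored = _scored_from_profiles(profiles)
    sizes = []
    for c in (0.01, 0.05, 0.1, 0.2, 0.4):
        spans = identify_clusters(scored, ClusterConfig(K=K, threshold=c))
        sizes.append(sum(s.size - 1 for s in spans))  # number of linked pairs
    assert sizes == sorted(sizes, reverse=True)


# --- within-cluster shares and topic sums ------------------------------

def test_within_cluster_error_share_extremes(make_profile):
    p = make_profile({0: 0.9})
    scored = [
        ScoredResponse(0, "a", 1.0, CORRECT, 0, p),
        ScoredResponse(1, "b", 2.0, PERSEVERATION, 0, p),
        ScoredResponse(2, "c", 3.0, INTRUSION, 2, make_profile({5: 0.9})),
    ]
    clusters = identify_clusters(scored, ClusterConfig(K=14))
    shares = within_cluster_error_share(scored, clusters)
    assert shares[PERSEVERATION] == 1.0   # inside the a-b cluster
    assert shares[INTRUSION] == 0.0
    assert within_cluster_error_share([], [])[PERSEVERATION] is None


def test_summed_topic_probabilities_conserve_count(make_profile):
    profiles = [make_profile({1: 0.7}), make_profile({2: 0.6}), None]
    scored = [ScoredResponse(i, "w", float(i), CORRECT, i, p)
              for i, p in enumerate(profiles)]
    ts = summed_topic_probabilities(scored, 14)
    assert ts.n_profiled == 2 and ts.n_skipped == 1
    assert ts.values.sum() == pytest.approx(2.0, abs=1e-8)
    np.testing.assert_allclose(ts.values, profiles[0] + profiles[1], atol=1e-12)


def test_error_topic_correlation_against_direct_formula():
    from vflda import TopicSum

    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([8.0, 6.0, 5.0, 1.0])

    def ts(v):
        return TopicSum(values=v, n_profiled=0, n_skipped=0)
    r = error_topic_correlation(ts(x), ts(y))
    expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert r == pytest.approx(expected, abs=1e-12)
    assert error_topic_correlation(ts(x), ts(x)) == pytest.approx(1.0)
    assert error_topic_correlation(ts(x), ts(np.ones(4))) is None
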