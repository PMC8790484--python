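"""Synthetic corpora and timed verbal-fluency cohorts with known ground truth.

Two generators drive every downstream stage:

* :func:`generate_corpus` draws bag-of-words documents from the standard LDA
  generative process with a planted topic-word matrix, so topic-model fits
  can be checked against the truth that produced the data.
* :func:`generate_transcript` / :func:`generate_cohort` emulate 60-second
  animal-fluency trials: correct responses arrive at declining per-phase
  rates, intrusions are out-of-category words attached to planted semantic
  subcategories, and perseverations repeat earlier responses after long lags.

Group profiles ship with defaults shaped like the three study populations:
young adults (no intrusions, rare perseverations), healthy older adults (few
errors), and mild-AD patients (an intrusion burst in the first 15 s and a
perseveration peak in the last 15 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CorpusSpec",
    "SyntheticCorpus",
    "GroupProfile",
    "Transcript",
    "GroundTruth",
    "generate_corpus",
    "generate_transcript",
    "generate_cohort",
    "generate_study_corpus",
    "ANIMAL_SUBCATEGORIES",
    "OUT_OF_CATEGORY",
    "DEFAULT_PROFILES",
    "MIN_ONSET_GAP",
]

#: minimal inter-onset gap enforced between consecutive responses (seconds)
MIN_ONSET_GAP = 0.3

# Planted semantic subcategories of the "animals" category.  Each key plays
# the role of one latent topic; OUT_OF_CATEGORY maps the same keys to
# semantically related non-animal words used as intrusions.
ANIMAL_SUBCATEGORIES: dict[str, list[str]] = {
    "farm": ["cow", "horse", "pig", "sheep", "goat", "chicken", "rooster",
             "duck", "donkey", "ox", "lamb", "goose"],
    "sea": ["fish", "whale", "dolphin", "shark", "seal", "octopus", "crab",
            "salmon", "cod", "herring", "lobster", "squid"],
    "birds": ["eagle", "owl", "sparrow", "crow", "seagull", "swallow",
              "falcon", "raven", "magpie", "swan", "pigeon", "ptarmigan"],
    "safari": ["lion", "tiger", "elephant", "giraffe", "zebra", "monkey",
               "gorilla", "chimpanzee", "kangaroo", "rhino", "hippo",
               "leopard"],
    "forest": ["moose", "reindeer", "fox", "wolf", "bear", "hare", "badger",
               "squirrel", "hedgehog", "lynx", "deer", "beaver"],
    "pets": ["dog", "cat", "rabbit", "hamster", "parrot", "canary",
             "guinea_pig", "turtle", "budgie", "ferret", "mouse", "rat"],
}

OUT_OF_CATEGORY: dict[str, list[str]] = {
    "farm": ["tractor", "barn", "hay", "plow"],
    "sea": ["boat", "seaweed", "anchor", "net"],
    "birds": ["nest", "feather", "birdhouse", "binoculars"],
    "safari": ["jungle", "savanna", "jeep", "rose"],
    "forest": ["pine", "mushroom", "rifle", "cabin"],
    "pets": ["leash", "cage", "aquarium", "collar"],
}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the planted-LDA corpus generator."""

    n_topics_true: int
    vocab_per_topic: int
    vocab_shared: int = 0
    n_docs: int = 200
    doc_length_mean: float = 30.0
    alpha_true: float = 0.3  # document-topic Dirichlet concentration
    beta_true: float = 0.1   # leak weight of foreign words in a topic row
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics_true < 1:
            raise ValueError("n_topics_true must be >= 1")
        if self.vocab_per_topic < 1:
            raise ValueError("vocab_per_topic must be >= 1")
        if self.vocab_shared < 0:
            raise ValueError("vocab_shared must be >= 0")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be > 0")
        if self.alpha_true <= 0 or self.beta_true <= 0:
            raise ValueError("concentration parameters must be > 0")


@dataclass
class SyntheticCorpus:
    documents: list[list[str]]
    vocabulary: list[str]
    topic_word: np.ndarray        # true K x V row-stochastic matrix
    doc_topic: np.ndarray         # true per-document topic mixtures
    topic_vocabularies: list[list[str]]


def _planted_topic_word(
    topic_words: Sequence[Sequence[str]],
    shared_words: Sequence[str],
    beta_true: float,
) -> tuple[list[str], np.ndarray]:
    vocab: list[str] = []
    for words in topic_words:
        vocab.extend(words)
    vocab.extend(shared_words)
    if len(set(vocab)) != len(vocab):
        raise ValueError("topic vocabularies must be disjoint")
    K, V = len(topic_words), len(vocab)
    own = np.zeros((K, V))
    pos = 0
    for k, words in enumerate(topic_words):
        own[k, pos:pos + len(words)] = 1.0
        pos += len(words)
    weights = np.full((K, V), beta_true)
    weights[:, V - len(shared_words):] = 0.5 if shared_words else beta_true
    weights[own > 0] = 1.0
    return vocab, weights / weights.sum(axis=1, keepdims=True)


def generate_corpus(
    spec: CorpusSpec,
    topic_words: Optional[Sequence[Sequence[str]]] = None,
    shared_words: Optional[Sequence[str]] = None,
) -> SyntheticCorpus:
    """Sample documents from the LDA generative process.

    Each document draws a topic mixture from Dirichlet(alpha_true), then each
    word draws a topic from the mixture and a token from that topic's row of
    the planted topic-word matrix.  Custom ``topic_words`` (one word list per
    topic) may replace the default synthetic tokens.
    """
    if topic_words is None:
        topic_words = [
            [f"t{k}w{j}" for j in range(spec.vocab_per_topic)]
            for k in range(spec.n_topics_true)
        ]
    if len(topic_words) != spec.n_topics_true:
        raise ValueError("topic_words must have one word list per true topic")
    if shared_words is None:
        shared_words = [f"shared{j}" for j in range(spec.vocab_shared)]

    vocab, phi = _planted_topic_word(topic_words, shared_words, spec.beta_true)
    K = spec.n_topics_true
    rng = np.random.default_rng(spec.seed)
    theta = rng.dirichlet(np.full(K, spec.alpha_true), size=spec.n_docs)
    lengths = np.maximum(rng.poisson(spec.doc_length_mean, size=spec.n_docs), 1)
    docs: list[list[str]] = []
    for d in range(spec.n_docs):
        z = rng.choice(K, size=lengths[d], p=theta[d])
        words = [vocab[rng.choice(len(vocab), p=phi[k])] for k in z]
        docs.append(words)
    return SyntheticCorpus(
        documents=docs,
        vocabulary=vocab,
        topic_word=phi,
        doc_topic=theta,
        topic_vocabularies=[list(w) for w in topic_words],
    )


def generate_study_corpus(
    seed: int = 0,
    n_docs: int = 400,
    doc_length_mean: float = 40.0,
    alpha_true: float = 0.3,
    beta_true: float = 0.02,
) -> SyntheticCorpus:
    """A corpus over the built-in animal subcategories plus their related
    out-of-category words, so intrusions acquire topic profiles too."""
    topic_words = [
        ANIMAL_SUBCATEGORIES[name] + OUT_OF_CATEGORY[name]
        for name in ANIMAL_SUBCATEGORIES
    ]
    spec = CorpusSpec(
        n_topics_true=len(topic_words),
        vocab_per_topic=max(len(w) for w in topic_words),
        vocab_shared=0,
        n_docs=n_docs,
        doc_length_mean=doc_length_mean,
        alpha_true=alpha_true,
        beta_true=beta_true,
        seed=seed,
    )
    return generate_corpus(spec, topic_words=topic_words, shared_words=[])


@dataclass(frozen=True)
class GroupProfile:
    """Behavioural profile of one participant group.

    ``rate_per_phase`` are expected correct responses per 15-s phase; the
    error rates are expected injections per phase.  ``topic_coherence`` in
    [0, 1] is the probability of staying in the current subcategory from one
    correct response to the next (1 = never switch).
    """

    label: str
    rate_per_phase: tuple[float, float, float, float]
    intrusion_rate_per_phase: tuple[float, float, float, float] = (0, 0, 0, 0)
    perseveration_rate_per_phase: tuple[float, float, float, float] = (0, 0, 0, 0)
    perseveration_lag_mean: float = 22.0
    topic_coherence: float = 0.6
    #: probability an intrusion attaches to the currently active subcategory
    intrusion_cluster_prob: float = 0.56

    def __post_init__(self) -> None:
        for rates in (self.rate_per_phase, self.intrusion_rate_per_phase,
                      self.perseveration_rate_per_phase):
            if len(rates) != 4:
                raise ValueError("rate vectors must have 4 entries (one per phase)")
            if any(r < 0 for r in rates):
                raise ValueError("rates must be non-negative")
        if self.perseveration_lag_mean <= 0:
            raise ValueError("perseveration_lag_mean must be > 0")
        if not 0.0 <= self.topic_coherence <= 1.0:
            raise ValueError("topic_coherence must lie in [0, 1]")


# Defaults shaped like the study populations: per-group correct totals
# 20.6 / 18.8 / 12.9, intrusion totals 0 / 0.09 / 0.95 with the AD burst in
# phase 1, perseveration totals 0.46 / 0.87 / 1.26 with the AD peak in
# phase 4, and ~22-s perseveration lags.
DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "young": GroupProfile(
        label="young",
        rate_per_phase=(7.4, 5.6, 4.3, 3.3),
        intrusion_rate_per_phase=(0.0, 0.0, 0.0, 0.0),
        perseveration_rate_per_phase=(0.115, 0.115, 0.115, 0.115),
    ),
    "older": GroupProfile(
        label="older",
        rate_per_phase=(6.8, 5.2, 3.9, 2.9),
        intrusion_rate_per_phase=(0.03, 0.02, 0.02, 0.02),
        perseveration_rate_per_phase=(0.20, 0.22, 0.22, 0.23),
    ),
    "ad": GroupProfile(
        label="ad",
        rate_per_phase=(4.8, 3.7, 2.9, 1.5),
        intrusion_rate_per_phase=(0.50, 0.20, 0.15, 0.10),
        perseveration_rate_per_phase=(0.10, 0.25, 0.38, 0.53),
    ),
}


@dataclass
class Transcript:
    """One subject's ordered, time-stamped responses in a 60-s trial."""

    subject_id: str
    group: str
    responses: list[tuple[str, float]]
    duration: float = 60.0

    def __post_init__(self) -> None:
        onsets = [t for _, t in self.responses]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.duration):
            raise ValueError(f"onsets must lie in [0, {self.duration})")

    def __len__(self) -> int:
        return len(self.responses)


@dataclass
class GroundTruth:
    """Injected labels and planted structure aligned with a transcript."""

    labels: list[str]             # correct | perseveration | intrusion
    planted_topics: list[int]     # subcategory index, -1 if none
    cluster_spans: list[list[int]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def _phase_counts(rng: np.random.Generator, rates: Sequence[float]) -> np.ndarray:
    return rng.poisson(np.asarray(rates, dtype=float))


def _enforce_gap(events: list[list], duration: float) -> list[list]:
    """Sort by onset and jitter forward to keep a MIN_ONSET_GAP spacing;
    events pushed past the trial end are dropped."""
    events.sort(key=lambda e: e[0])
    kept: list[list] = []
    for ev in events:
        if kept and ev[0] < kept[-1][0] + MIN_ONSET_GAP:
            ev = [kept[-1][0] + MIN_ONSET_GAP, *ev[1:]]
        if ev[0] < duration:
            kept.append(ev)
    return kept


def _planted_spans(topics: Sequence[int]) -> list[list[int]]:
    spans: list[list[int]] = []
    i = 0
    n = len(topics)
    while i < n:
        if topics[i] < 0:
            i += 1
            continue
        j = i
        while j + 1 < n and topics[j + 1] == topics[i]:
            j += 1
        if j > i:
            spans.append(list(range(i, j + 1)))
        i = j + 1
    return spans


def generate_transcript(
    profile: GroupProfile,
    subcategories: Mapping[str, Sequence[str]] = ANIMAL_SUBCATEGORIES,
    seed: int = 0,
    out_of_category: Mapping[str, Sequence[str]] = OUT_OF_CATEGORY,
    subject_id: str = "s0",
    duration: float = 60.0,
    phase_length: float = 15.0,
) -> tuple[Transcript, GroundTruth]:
    """Simulate one timed trial with known injected labels.

    Correct-response onsets follow an inhomogeneous Poisson process with the
    profile's per-phase rates; words walk across planted subcategories with
    the profile's coherence and never repeat.  Intrusions are out-of-category
    words attached to a subcategory (usually the active one).  Perseverations
    repeat an earlier response, placed at the profile's per-phase rates with
    the source chosen by an exponential lag preference.
    """
    for rates in (profile.rate_per_phase, profile.intrusion_rate_per_phase,
                  profile.perseveration_rate_per_phase):
        if any(r > phase_length / MIN_ONSET_GAP for r in rates):
            raise ValueError(
                "per-phase rate exceeds the minimal inter-onset gap capacity "
                f"({phase_length / MIN_ONSET_GAP:.0f} per phase)"
            )
    rng = np.random.default_rng(seed)
    subcat_names = list(subcategories)
    n_sub = len(subcat_names)
    phase_starts = np.arange(4) * phase_length

    # --- correct responses ---------------------------------------------
    onsets: list[float] = []
    for p, rate in enumerate(profile.rate_per_phase):
        k = rng.poisson(rate)
        onsets.extend(phase_starts[p] + rng.uniform(0, phase_length, size=k))
    onsets.sort()

    remaining = {name: list(rng.permutation(list(words)))
                 for name, words in subcategories.items()}
    current = int(rng.integers(n_sub))
    events: list[list] = []  # [onset, word, label, planted_topic]
    for t in onsets:
        if rng.random() > profile.topic_coherence and n_sub > 1:
            current = int(rng.choice([k for k in range(n_sub) if k != current]))
        if not remaining[subcat_names[current]]:
            with_words = [k for k in range(n_sub)
                          if remaining[subcat_names[k]]]
            if not with_words:
                break
            current = int(rng.choice(with_words))
        word = remaining[subcat_names[current]].pop()
        events.append([float(t), word, "correct", current])

    # --- intrusions ------------------------------------------------------
    intrusion_pool = {name: list(rng.permutation(list(words)))
                      for name, words in out_of_category.items()}
    correct_events = sorted(events, key=lambda e: e[0])
    for p, rate in enumerate(profile.intrusion_rate_per_phase):
        for _ in range(rng.poisson(rate)):
            t = float(phase_starts[p] + rng.uniform(0, phase_length))
            if correct_events and rng.random() < profile.intrusion_cluster_prob:
                nearest = min(correct_events, key=lambda e: abs(e[0] - t))
                topic = nearest[3]
            else:
                topic = int(rng.integers(n_sub))
            pool = intrusion_pool[subcat_names[topic]]
            if not pool:
                alt = [k for k in range(n_sub) if intrusion_pool[subcat_names[k]]]
                if not alt:
                    continue
                topic = int(rng.choice(alt))
                pool = intrusion_pool[subcat_names[topic]]
            events.append([t, pool.pop(), "intrusion", topic])

    # --- perseverations --------------------------------------------------
    for p, rate in enumerate(profile.perseveration_rate_per_phase):
        for _ in range(rng.poisson(rate)):
            t = float(phase_starts[p] + rng.uniform(0, phase_length))
            earlier = [e for e in events if e[0] < t and e[2] != "perseveration"]
            if not earlier:
                continue
            lags = np.array([t - e[0] for e in earlier])
            w = np.exp(-lags / profile.perseveration_lag_mean)
            src = earlier[rng.choice(len(earlier), p=w / w.sum())]
            events.append([t, src[1], "perseveration", src[3]])

    events = _enforce_gap(events, duration)
    transcript = Transcript(
        subject_id=subject_id,
        group=profile.label,
        responses=[(e[1], e[0]) for e in events],
        duration=duration,
    )
    topics = [e[3] for e in events]
    truth = GroundTruth(
        labels=[e[2] for e in events],
        planted_topics=topics,
        cluster_spans=_planted_spans(topics),
    )
    return transcript, truth


def generate_cohort(
    n_per_group: Mapping[str, int],
    profiles: Mapping[str, GroupProfile] = DEFAULT_PROFILES,
    subcategories: Mapping[str, Sequence[str]] = ANIMAL_SUBCATEGORIES,
    out_of_category: Mapping[str, Sequence[str]] = OUT_OF_CATEGORY,
    seed: int = 0,
) -> list[tuple[Transcript, GroundTruth]]:
    """Simulate a cohort; per-subject sub-seeds derive reproducibly from
    the root seed, so identical inputs give identical cohorts."""
    unknown = set(n_per_group) - set(profiles)
    if unknown:
        raise KeyError(f"no profile for group(s): {sorted(unknown)}")
    total = sum(n_per_group.values())
    sub_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1)) % (2**31)
    cohort: list[tuple[Transcript, GroundTruth]] = []
    i = 0
    for group, n in n_per_group.items():
        for j in range(n):
            cohort.append(
                generate_transcript(
                    profiles[group],
                    subcategories=subcategories,
                    out_of_category=out_of_category,
                    seed=int(sub_seeds[i]),
                    subject_id=f"{group}_{j:03d}",
                )
            )
            i += 1
    return cohort
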