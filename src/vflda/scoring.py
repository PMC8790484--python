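"""Scoring of timed verbal-fluency transcripts and topic-based cluster analysis.

A 60-second semantic fluency trial yields an ordered sequence of responses.
Each response is classified as *correct* (a first production of a category
word), *perseveration* (a repetition of any previously produced word),
*intrusion* (a first production outside the category that is nevertheless a
real, profiled word), or *non-word* (an utterance with no topic profile at
all).  Clusters — runs of consecutive responses bound to the same semantic
subcategory — are identified from per-word topic-probability vectors: two
adjacent responses are linked when some topic exceeds the criterion
``c = (1/K) * 0.5`` in both.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .synthetic import Transcript

__all__ = [
    "Lexicon",
    "ScoredResponse",
    "ClusterConfig",
    "ClusterSpan",
    "Transposition",
    "TopicSum",
    "normalize_word",
    "lookup_profile",
    "score_transcript",
    "cluster_threshold",
    "identify_clusters",
    "within_cluster_error_share",
    "summed_topic_probabilities",
    "error_topic_correlation",
    "CORRECT",
    "PERSEVERATION",
    "INTRUSION",
    "NONWORD",
    "ERROR_LABELS",
]

CORRECT = "correct"
PERSEVERATION = "perseveration"
INTRUSION = "intrusion"
NONWORD = "nonword"
#: non-words are a distinct internal label but count with intrusions in totals
ERROR_LABELS = (PERSEVERATION, INTRUSION, NONWORD)

_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_word(raw: str) -> Optional[str]:
    """Normalize a raw utterance to a lookup token.

    Lowercase, NFC unicode, punctuation stripped, internal whitespace
    collapsed to a single underscore (``"rose bed"`` -> ``"rose_bed"``).
    Returns ``None`` when nothing is left after normalization (the explicit
    empty-token signal).
    """
    token = unicodedata.normalize("NFC", raw).lower()
    token = _PUNCT_RE.sub("", token)
    token = _WS_RE.sub("_", token.strip())
    return token or None


@dataclass(frozen=True)
class Lexicon:
    """The set of words counted as members of the fluency category."""

    category_words: frozenset[str]
    category_name: str = "animals"

    def __post_init__(self) -> None:
        if not self.category_words:
            raise ValueError("lexicon must be non-empty")
        norm = frozenset(t for t in (normalize_word(w) for w in self.category_words) if t)
        object.__setattr__(self, "category_words", norm)

    def __contains__(self, token: str) -> bool:
        return token in self.category_words


@dataclass
class ScoredResponse:
    index: int
    word: str  # normalized token ("" for utterances empty after normalization)
    onset: float
    label: str
    first_occurrence_index: int
    profile: Optional[np.ndarray]  # K-vector summing to 1, or None ("no profile")

    @property
    def is_error(self) -> bool:
        return self.label in ERROR_LABELS


def lookup_profile(
    token: Optional[str], profiles: Mapping[str, np.ndarray]
) -> Optional[np.ndarray]:
    """Topic profile for a token, with the multiword fallback.

    The joined token is looked up first; failing that, the profile is the
    normalized mean of the constituent tokens' profiles; if no constituent
    is known either, the result is ``None`` (no profile).
    """
    if token is None:
        return None
    hit = profiles.get(token)
    if hit is not None:
        return np.asarray(hit, dtype=float)
    if "_" in token:
        parts = [profiles[p] for p in token.split("_") if p in profiles]
        if parts:
            mean = np.mean(np.asarray(parts, dtype=float), axis=0)
            total = mean.sum()
            if total > 0:
                return mean / total
    return None


def score_transcript(
    transcript: Transcript,
    lexicon: Lexicon,
    profiles: Mapping[str, np.ndarray],
) -> list[ScoredResponse]:
    """Label every response of a transcript.

    Rules: a repetition of ANY previously produced word (correct or not) is a
    perseveration — the clinical definition is over words, not correct
    words, and immediate repetitions count (repeated at any point).  First
    productions inside the lexicon are correct; first productions outside it
    are intrusions when a topic profile exists and non-words otherwise.
    """
    onsets = [onset for _, onset in transcript.responses]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("transcript onsets must be strictly increasing")

    scored: list[ScoredResponse] = []
    first_seen: dict[str, int] = {}
    for i, (raw, onset) in enumerate(transcript.responses):
        token = normalize_word(raw)
        profile = lookup_profile(token, profiles)
        if token is not None and token in first_seen:
            label = PERSEVERATION
            first = first_seen[token]
        else:
            first = i
            if token is None:
                label = NONWORD
            elif token in lexicon:
                label = CORRECT
            elif profile is not None:
                label = INTRUSION
            else:
                label = NONWORD
            if token is not None:
                first_seen[token] = i
        scored.append(
            ScoredResponse(
                index=i,
                word=token or "",
                onset=onset,
                label=label,
                first_occurrence_index=first,
                profile=profile,
            )
        )
    return scored


def cluster_threshold(K: int) -> float:
    """Cluster criterion c = (1/K) x 0.5; with the study's K = 14, 1/28."""
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    return (1.0 / K) * 0.5


@dataclass(frozen=True)
class ClusterConfig:
    K: int
    threshold: float | None = None
    min_run: int = 2

    def __post_init__(self) -> None:
        if self.threshold is None:
            object.__setattr__(self, "threshold", cluster_threshold(self.K))
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class Transposition:
    position: int  # response index at which the linking topic set changes
    from_topics: frozenset[int]
    to_topics: frozenset[int]


@dataclass
class ClusterSpan:
    member_indices: list[int]
    pair_topics: list[frozenset[int]]  # one set per adjacent pair
    transpositions: list[Transposition] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def __contains__(self, index: int) -> bool:
        return index in self.member_indices


def _shared_topics(
    a: Optional[np.ndarray], b: Optional[np.ndarray], c: float
) -> frozenset[int]:
    if a is None or b is None:
        return frozenset()
    return frozenset(np.flatnonzero((a > c) & (b > c)).tolist())


def identify_clusters(
    scored: Sequence[ScoredResponse], config: ClusterConfig
) -> list[ClusterSpan]:
    """Maximal runs of consecutive responses joined by shared topics.

    Adjacent pair (i, i+1) is linked iff some topic exceeds the threshold in
    both profiles (strictly greater).  Responses without a profile can never
    link; error responses participate.  A transposition is logged at the left
    response of a pair whose shared-topic set is disjoint from the previous
    pair's, while the run stays linked.
    """
    c = config.threshold
    for r in scored:
        if r.profile is not None and len(r.profile) != config.K:
            raise ValueError(
                f"profile length {len(r.profile)} does not match K={config.K}"
            )
    n = len(scored)
    linked = [
        _shared_topics(scored[i].profile, scored[i + 1].profile, c)
        for i in range(n - 1)
    ]
    spans: list[ClusterSpan] = []
    i = 0
    while i < n - 1:
        if not linked[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and linked[j]:
            j += 1
        members = list(range(i, j + 1))
        pair_topics = linked[i:j]
        transpositions = [
            Transposition(
                position=scored[i + p].index,
                from_topics=pair_topics[p - 1],
                to_topics=pair_topics[p],
            )
            for p in range(1, len(pair_topics))
            if pair_topics[p].isdisjoint(pair_topics[p - 1])
        ]
        spans.append(
            ClusterSpan(
                member_indices=[scored[k].index for k in members],
                pair_topics=pair_topics,
                transpositions=transpositions,
            )
        )
        i = j + 1
    return spans


def within_cluster_error_share(
    scored: Sequence[ScoredResponse], clusters: Sequence[ClusterSpan]
) -> dict[str, Optional[float]]:
    """Proportion of each error type produced inside a cluster.

    Non-words count in the intrusion denominator (they are tallied with
    intrusions) but can never lie inside a cluster.  ``None`` flags an
    undefined share (no errors of that type).
    """
    in_cluster = set()
    for span in clusters:
        in_cluster.update(span.member_indices)
    shares: dict[str, Optional[float]] = {}
    for key, labels in ((PERSEVERATION, {PERSEVERATION}), (INTRUSION, {INTRUSION, NONWORD})):
        events = [r for r in scored if r.label in labels]
        if not events:
            shares[key] = None
        else:
            inside = sum(1 for r in events if r.index in in_cluster)
            shares[key] = inside / len(events)
    return shares


@dataclass
class TopicSum:
    """Per-topic aggregate of topic probabilities over a response subset."""

    values: np.ndarray
    n_profiled: int
    n_skipped: int
    descriptor: str = ""


def summed_topic_probabilities(
    scored: Iterable[ScoredResponse], K: int, descriptor: str = ""
) -> TopicSum:
    """Component k is the sum of profile[k] over profiled responses.

    The total across topics equals the number of profiled responses, because
    each profile sums to one; unprofiled responses are skipped and counted.
    """
    total = np.zeros(K, dtype=float)
    n_profiled = 0
    n_skipped = 0
    for r in scored:
        if r.profile is None:
            n_skipped += 1
            continue
        if len(r.profile) != K:
            raise ValueError("profile length does not match K")
        total += r.profile
        n_profiled += 1
    return TopicSum(values=total, n_profiled=n_profiled, n_skipped=n_skipped,
                    descriptor=descriptor)


def error_topic_correlation(
    error_sum: TopicSum, model_sum: TopicSum
) -> Optional[float]:
    """Pearson r across the K paired topic components.

    Returns ``None`` (undefined-correlation signal) when either vector has
    zero variance.
    """
    x = np.asarray(error_sum.values, dtype=float)
    y = np.asarray(model_sum.values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("topic sums must have equal K")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
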