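"""LDA topic models over bag-of-words corpora and per-word topic profiles.

The model here is standard latent Dirichlet allocation: each document mixes
K latent topics (Dirichlet(alpha) prior), each topic is a distribution over
the vocabulary.  Fitting is delegated to scikit-learn's batch variational
inference with a fixed seed; everything built on top of the fitted matrices
— the hyperparameter grid, held-out document-completion model selection, the
corpus-level topic prevalence, and the per-word posterior
``p(topic | word) ∝ phi[topic, word] * prevalence[topic]`` — lives in this
module.

A word's K-vector of topic probabilities sums to 1; words absent from the
fitted vocabulary have no profile (they are flagged, never invented).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.model_selection import KFold

from .scoring import normalize_word

__all__ = [
    "LdaConfig",
    "TopicModel",
    "WordTopicProfile",
    "tokenize_corpus",
    "restrict_corpus",
    "fit_lda",
    "model_grid",
    "select_model",
    "word_topic_probabilities",
    "profile_table",
    "table_to_profiles",
    "STUDY_K_VALUES",
    "STUDY_ALPHA_VALUES",
]

#: the study's hyperparameter grid: K = 3..15 crossed with 5 alphas (65 models)
STUDY_K_VALUES: tuple[int, ...] = tuple(range(3, 16))
STUDY_ALPHA_VALUES: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 1.0)

Document = Union[str, Sequence[str]]


@dataclass(frozen=True)
class LdaConfig:
    n_topics: int
    alpha: float
    seed: int = 0
    n_iterations: int = 100
    convergence_tol: float = 1e-3
    topic_word_prior: float = 0.1

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class TopicModel:
    K: int
    alpha: float
    vocabulary: list[str]
    topic_word: np.ndarray        # K x V, each row sums to 1
    topic_prevalence: np.ndarray  # K, sums to 1
    heldout_score: Optional[float] = None
    seed: int = 0
    word_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.word_index:
            self.word_index = {w: i for i, w in enumerate(self.vocabulary)}


@dataclass
class WordTopicProfile:
    word: str
    probabilities: np.ndarray  # length K, sums to 1


def tokenize_corpus(corpus: Iterable[Document]) -> list[list[str]]:
    """Normalize every document to a list of lookup tokens."""
    docs: list[list[str]] = []
    for doc in corpus:
        raw_tokens = doc.split() if isinstance(doc, str) else doc
        tokens = [t for t in (normalize_word(w) for w in raw_tokens) if t]
        docs.append(tokens)
    return docs


def restrict_corpus(
    corpus: Sequence[Document], wordlist: Iterable[str]
) -> list[Document]:
    """Documents containing at least one wordlist token, order preserved."""
    wanted = {t for t in (normalize_word(w) for w in wordlist) if t}
    if not wanted:
        raise ValueError("wordlist is empty after normalization")
    tokenized = tokenize_corpus(corpus)
    return [doc for doc, toks in zip(corpus, tokenized)
            if any(t in wanted for t in toks)]


def _doc_term_matrix(
    docs: list[list[str]], vocabulary: Optional[list[str]] = None
) -> tuple[sparse.csr_matrix, list[str]]:
    if vocabulary is None:
        vocabulary = sorted({t for doc in docs for t in doc})
    index = {w: i for i, w in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for d, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for t in doc:
            j = index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(d)
            cols.append(j)
            data.append(c)
    X = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=float
    )
    return X, vocabulary


def fit_lda(corpus: Sequence[Document], config: LdaConfig) -> TopicModel:
    """Fit LDA and return row-stochastic topic-word and prevalence estimates.

    Topic prevalence is the length-weighted mean of the document-topic
    posteriors, i.e. the expected share of corpus tokens carried by each
    topic.  Deterministic under a fixed seed and iteration budget.
    """
    docs = tokenize_corpus(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    X, vocab = _doc_term_matrix(docs)
    if not vocab:
        raise ValueError("corpus has an empty vocabulary after normalization")
    if config.n_topics > len(vocab):
        raise ValueError(
            f"K={config.n_topics} exceeds vocabulary size {len(vocab)}"
        )
    lda = LatentDirichletAllocation(
        n_components=config.n_topics,
        doc_topic_prior=config.alpha,
        topic_word_prior=config.topic_word_prior,
        learning_method="batch",
        max_iter=config.n_iterations,
        evaluate_every=5,
        perp_tol=config.convergence_tol,
        random_state=config.seed,
    )
    theta = lda.fit_transform(X)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    lengths = np.asarray(X.sum(axis=1)).ravel()
    weights = lengths / lengths.sum() if lengths.sum() > 0 else np.full(len(docs), 1 / len(docs))
    prevalence = weights @ theta
    prevalence = prevalence / prevalence.sum()
    return TopicModel(
        K=config.n_topics,
        alpha=config.alpha,
        vocabulary=vocab,
        topic_word=phi,
        topic_prevalence=prevalence,
        seed=config.seed,
    )


def model_grid(
    K_values: Iterable[int],
    alpha_values: Iterable[float],
    seed: int = 0,
    n_iterations: int = 100,
) -> list[LdaConfig]:
    """Full Cartesian product of the hyperparameter grid, K-major order.

    The study grid (K = 3..15, alpha in {0.2, 0.3, 0.4, 0.5, 1}) enumerates
    65 configurations.
    """
    K_values = list(K_values)
    alpha_values = list(alpha_values)
    if not K_values or not alpha_values:
        raise ValueError("K_values and alpha_values must be non-empty")
    return [
        LdaConfig(n_topics=K, alpha=a, seed=seed, n_iterations=n_iterations)
        for K, a in itertools.product(K_values, alpha_values)
    ]


def _fold_in_theta(
    counts: np.ndarray, phi: np.ndarray, alpha: float, n_iter: int = 50
) -> np.ndarray:
    """Posterior document-topic mixture for a bag of word counts by a
    fixed-point EM on the variational objective (phi held fixed)."""
    K = phi.shape[0]
    theta = np.full(K, 1.0 / K)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return theta
    c = counts[nz]
    phi_nz = phi[:, nz]  # K x m
    for _ in range(n_iter):
        q = phi_nz * theta[:, None]  # K x m
        q_sum = q.sum(axis=0)
        q_sum[q_sum == 0] = 1.0
        gamma = alpha + (q / q_sum) @ c
        theta = gamma / gamma.sum()
    return theta


def _completion_loglik(
    test_docs: list[list[str]], model: TopicModel
) -> tuple[float, int]:
    """Document-completion log-likelihood: infer the topic mixture from the
    even-index half of each document, evaluate the odd-index half."""
    total, n_tokens = 0.0, 0
    eps = 1e-12
    for doc in test_docs:
        known = [t for t in doc if t in model.word_index]
        if len(known) < 2:
            continue
        first, second = known[0::2], known[1::2]
        counts = np.zeros(len(model.vocabulary))
        for t in first:
            counts[model.word_index[t]] += 1
        theta = _fold_in_theta(counts, model.topic_word, model.alpha)
        mix = theta @ model.topic_word  # predictive word distribution
        for t in second:
            total += np.log(mix[model.word_index[t]] + eps)
            n_tokens += 1
    return total, n_tokens


def select_model(
    corpus: Sequence[Document],
    configs: Sequence[LdaConfig],
    folds: Union[int, str] = 5,
    seed: int = 0,
) -> tuple[TopicModel, pd.DataFrame]:
    """Fit every candidate configuration and pick the best by held-out
    document-completion log-likelihood.

    Documents are split into k folds (``folds="loo"`` for leave-one-out);
    each fold is scored under a model fit on the remaining documents.  Ties
    break toward smaller K, then smaller alpha (parsimony).  Returns the
    winning model refit on the full corpus plus the complete score table.
    """
    if not configs:
        raise ValueError("at least one configuration is required")
    docs = tokenize_corpus(corpus)
    n_docs = len(docs)
    n_splits = n_docs if folds == "loo" else int(folds)
    if n_splits < 2 or n_splits > n_docs:
        raise ValueError(
            f"corpus of {n_docs} documents cannot support {folds} folds"
        )
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(kf.split(np.arange(n_docs)))

    rows = []
    for cfg in configs:
        total, n_tokens = 0.0, 0
        for train_idx, test_idx in splits:
            train = [docs[i] for i in train_idx]
            test = [docs[i] for i in test_idx]
            fitted = fit_lda(train, cfg)
            ll, nt = _completion_loglik(test, fitted)
            total += ll
            n_tokens += nt
        per_token = total / n_tokens if n_tokens else -np.inf
        rows.append({"K": cfg.n_topics, "alpha": cfg.alpha,
                     "heldout_loglik_per_token": per_token})
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(configs)),
        key=lambda i: (-rows[i]["heldout_loglik_per_token"],
                       configs[i].n_topics, configs[i].alpha),
    )
    best_cfg = configs[order[0]]
    best = fit_lda(corpus, best_cfg)
    best.heldout_score = rows[order[0]]["heldout_loglik_per_token"]
    return best, table


def word_topic_probabilities(
    model: TopicModel, word: str
) -> Optional[WordTopicProfile]:
    """p(topic | word) under the model, or ``None`` for unknown words.

    Bayes with the corpus-level prevalence as the prior over topics:
    ``p(k | w) = phi[k, w] * prevalence[k] / sum_j phi[j, w] * prevalence[j]``.
    The resulting K-vector sums to 1.
    """
    token = normalize_word(word)
    if token is None or token not in model.word_index:
        return None
    j = model.word_index[token]
    joint = model.topic_word[:, j] * model.topic_prevalence
    total = joint.sum()
    if total == 0:
        return None
    return WordTopicProfile(word=token, probabilities=joint / total)


def profile_table(model: TopicModel, wordlist: Iterable[str]) -> pd.DataFrame:
    """One row per wordlist entry: ``word, known, k1..kK``.

    Unknown words are flagged (``known=False``) with NaN probabilities,
    mirroring utterances that have no topic probabilities.
    """
    cols = [f"k{i + 1}" for i in range(model.K)]
    rows = []
    for word in wordlist:
        prof = word_topic_probabilities(model, word)
        token = normalize_word(word) or ""
        if prof is None:
            rows.append([token, False] + [np.nan] * model.K)
        else:
            rows.append([prof.word, True] + list(prof.probabilities))
    return pd.DataFrame(rows, columns=["word", "known"] + cols)


def table_to_profiles(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Mapping word -> K-vector from a profile table (unknown rows dropped)."""
    cols = [c for c in table.columns if c.startswith("k") and c[1:].isdigit()]
    out: dict[str, np.ndarray] = {}
    for _, row in table.iterrows():
        if bool(row.get("known", True)) and not np.isnan(row[cols[0]]):
            out[str(row["word"])] = row[cols].to_numpy(dtype=float)
    return out
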