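"""Plain-text file formats: transcripts, lexica, corpora, profile tables,
scored transcripts, and persisted topic models.  Everything is TSV or
line-per-record UTF-8 text so that runs are diffable and portable."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scoring import ClusterSpan, Lexicon, ScoredResponse
from .synthetic import GroundTruth, Transcript
from .topic_model import TopicModel

__all__ = [
    "read_lexicon", "write_lexicon",
    "read_corpus", "write_corpus",
    "read_transcripts", "write_transcripts",
    "write_ground_truth", "read_ground_truth",
    "read_profile_table", "write_profile_table",
    "write_scored", "read_scored",
    "write_model", "read_model",
]

PathLike = Union[str, Path]
TRANSCRIPT_COLUMNS = ["subject_id", "group", "word", "onset_s"]
PROFILE_DECIMALS = 10


def read_lexicon(path: PathLike, category_name: str = "animals") -> Lexicon:
    words = [line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines()]
    return Lexicon(frozenset(w for w in words if w), category_name=category_name)


def write_lexicon(lexicon: Lexicon, path: PathLike) -> None:
    Path(path).write_text(
        "\n".join(sorted(lexicon.category_words)) + "\n", encoding="utf-8"
    )


def read_corpus(path: PathLike) -> list[list[str]]:
    """One document per line, whitespace-tokenized; blank lines skipped."""
    return [line.split() for line in
            Path(path).read_text(encoding="utf-8").splitlines() if line.strip()]


def write_corpus(documents: Iterable[Sequence[str]], path: PathLike) -> None:
    Path(path).write_text(
        "\n".join(" ".join(doc) for doc in documents) + "\n", encoding="utf-8"
    )


def read_transcripts(path: PathLike, trial_length: float = 60.0) -> list[Transcript]:
    """Transcript TSV with header ``subject_id group word onset_s``.

    Rows are grouped by subject in order of first appearance and sorted by
    onset within subject; malformed rows are rejected with their line number.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != TRANSCRIPT_COLUMNS:
        raise ValueError(
            f"{path}: expected header {' '.join(TRANSCRIPT_COLUMNS)!r}"
        )
    rows: dict[str, dict] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        subject, group, word, onset_s = parts
        try:
            onset = float(onset_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric onset {onset_s!r}") from None
        if onset < 0 or onset >= trial_length:
            raise ValueError(
                f"{path}:{lineno}: onset {onset} outside [0, {trial_length})"
            )
        entry = rows.setdefault(subject, {"group": group, "responses": []})
        if entry["group"] != group:
            raise ValueError(f"{path}:{lineno}: conflicting group for {subject!r}")
        entry["responses"].append((word, onset))
    transcripts = []
    for subject, entry in rows.items():
        responses = sorted(entry["responses"], key=lambda r: r[1])
        transcripts.append(Transcript(subject_id=subject, group=entry["group"],
                                      responses=responses, duration=trial_length))
    return transcripts


def write_transcripts(transcripts: Iterable[Transcript], path: PathLike) -> None:
    out = ["\t".join(TRANSCRIPT_COLUMNS)]
    for t in transcripts:
        for word, onset in t.responses:
            out.append(f"{t.subject_id}\t{t.group}\t{word}\t{onset:.6f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def write_ground_truth(
    items: Iterable[tuple[Transcript, GroundTruth]], path: PathLike
) -> None:
    out = ["subject_id\tindex\ttrue_label\tplanted_topic"]
    for transcript, truth in items:
        for i, (label, topic) in enumerate(zip(truth.labels, truth.planted_topics)):
            out.append(f"{transcript.subject_id}\t{i}\t{label}\t{topic}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_ground_truth(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile_table(table: pd.DataFrame, path: PathLike) -> None:
    """Profile TSV ``word k1 ... kK`` at 10 decimal digits; unknown words
    carry NA probabilities."""
    cols = [c for c in table.columns if c.startswith("k") and c[1:].isdigit()]
    out = ["\t".join(["word"] + cols)]
    for _, row in table.iterrows():
        vals = [
            "NA" if np.isnan(row[c]) else f"{row[c]:.{PROFILE_DECIMALS}f}"
            for c in cols
        ]
        out.append("\t".join([str(row["word"])] + vals))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_profile_table(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    cols = [c for c in table.columns if c.startswith("k") and c[1:].isdigit()]
    table.insert(1, "known", ~table[cols[0]].isna())
    return table


def write_scored(
    scored_by_subject: Mapping[str, tuple[str, Sequence[ScoredResponse],
                                          Sequence[ClusterSpan]]],
    path: PathLike,
) -> None:
    """Scored TSV: subject_id, index, word, onset_s, label,
    first_occurrence_index, cluster_id (-1 when outside any cluster)."""
    out = ["subject_id\tindex\tword\tonset_s\tlabel\tfirst_occurrence_index\tcluster_id"]
    for subject, (_, scored, clusters) in scored_by_subject.items():
        cluster_of = {}
        for cid, span in enumerate(clusters):
            for idx in span.member_indices:
                cluster_of[idx] = cid
        for r in scored:
            out.append(
                f"{subject}\t{r.index}\t{r.word}\t{r.onset:.6f}\t{r.label}"
                f"\t{r.first_occurrence_index}\t{cluster_of.get(r.index, -1)}"
            )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_scored(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_model(model: TopicModel, directory: PathLike) -> None:
    """Persist a model as two TSVs (topic-word matrix, prevalence) plus a
    key-value metadata file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tw = pd.DataFrame(model.topic_word, columns=model.vocabulary)
    tw.insert(0, "topic", np.arange(model.K))
    tw.to_csv(d / "topic_word.tsv", sep="\t", index=False,
              float_format=f"%.{PROFILE_DECIMALS}e")
    prev = pd.DataFrame({"topic": np.arange(model.K),
                         "prevalence": model.topic_prevalence})
    prev.to_csv(d / "prevalence.tsv", sep="\t", index=False,
                float_format=f"%.{PROFILE_DECIMALS}e")
    meta = {"K": model.K, "alpha": model.alpha, "seed": model.seed,
            "heldout_score": model.heldout_score}
    (d / "metadata.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_model(directory: PathLike) -> TopicModel:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text(encoding="utf-8"))
    tw = pd.read_csv(d / "topic_word.tsv", sep="\t")
    vocab = [c for c in tw.columns if c != "topic"]
    prev = pd.read_csv(d / "prevalence.tsv", sep="\t")["prevalence"].to_numpy()
    phi = tw[vocab].to_numpy(dtype=float)
    phi = phi / phi.sum(axis=1, keepdims=True)
    return TopicModel(
        K=int(meta["K"]), alpha=float(meta["alpha"]), vocabulary=vocab,
        topic_word=phi, topic_prevalence=prev / prev.sum(),
        heldout_score=meta.get("heldout_score"), seed=int(meta.get("seed", 0)),
    )
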