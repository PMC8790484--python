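"""End-to-end analysis pipeline over a cohort of timed fluency transcripts.

Stage order mirrors the study design: fit/select a topic model (or load a
precomputed word-profile table) -> derive per-word topic profiles -> score
each transcript -> identify clusters -> time-course summaries and error
intervals -> group statistics.  All randomness flows from one root seed via
stage-derived sub-seeds, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .group_stats import chisq_independence, median_split, mixed_anova, oneway_anova
from .scoring import (ClusterConfig, Lexicon, identify_clusters,
                      score_transcript, summed_topic_probabilities,
                      error_topic_correlation,
                      PERSEVERATION, INTRUSION, NONWORD)
from .synthetic import (ANIMAL_SUBCATEGORIES, DEFAULT_PROFILES,
                        generate_cohort, generate_study_corpus)
from .time_course import INTERVAL_MODES, error_intervals, phase_summary
from .topic_model import (model_grid, profile_table, restrict_corpus,
                          select_model, table_to_profiles)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("vflda")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; file paths are optional — any
    missing input is synthesized from the seed."""

    out_dir: str
    transcripts_path: Optional[str] = None
    corpus_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    profile_table_path: Optional[str] = None  # skips LDA fitting when given
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"young": 8, "older": 8, "ad": 8})
    K_values: tuple[int, ...] = (5, 6, 7)
    alpha_values: tuple[float, ...] = (0.3,)
    folds: int = 3
    n_iterations: int = 60
    phase_length: float = 15.0
    trial_length: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_length % self.phase_length != 0:
            raise ValueError("phase length must divide trial length")


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns a summary dict with the key tables and statistics.  Any stage
    failure surfaces as an exception naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    # --- stage: transcripts -------------------------------------------
    stage = "transcripts"
    try:
        if config.transcripts_path:
            transcripts = vio.read_transcripts(config.transcripts_path,
                                               config.trial_length)
            truths = None
        else:
            cohort = generate_cohort(config.n_per_group, seed=seeds[0])
            transcripts = [t for t, _ in cohort]
            truths = cohort
            vio.write_ground_truth(cohort, out / "ground_truth.tsv")
        vio.write_transcripts(transcripts, out / "transcripts.tsv")
        logger.info("stage %s: %d transcripts", stage, len(transcripts))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: lexicon ------------------------------------------------
    stage = "lexicon"
    try:
        if config.lexicon_path:
            lexicon = vio.read_lexicon(config.lexicon_path)
        else:
            lexicon = Lexicon(frozenset(
                w for words in ANIMAL_SUBCATEGORIES.values() for w in words))
        logger.info("stage %s: %d category words", stage, len(lexicon.category_words))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: topic profiles ----------------------------------------
    stage = "topic_profiles"
    try:
        response_words = sorted({w for t in transcripts for w, _ in t.responses})
        if config.profile_table_path:
            table = vio.read_profile_table(config.profile_table_path)
            model_meta = {"source": "precomputed", "K": sum(
                c.startswith("k") and c[1:].isdigit() for c in table.columns)}
            K = model_meta["K"]
        else:
            if config.corpus_path:
                corpus = vio.read_corpus(config.corpus_path)
            else:
                corpus = generate_study_corpus(seed=seeds[1]).documents
            corpus = restrict_corpus(corpus, response_words) or corpus
            configs = model_grid(config.K_values, config.alpha_values,
                                 seed=seeds[2], n_iterations=config.n_iterations)
            model, scores = select_model(corpus, configs, folds=config.folds,
                                         seed=seeds[2])
            scores.to_csv(out / "model_selection.tsv", sep="\t", index=False)
            vio.write_model(model, out / "model")
            table = profile_table(
                model, sorted(set(response_words) | lexicon.category_words))
            K = model.K
            model_meta = {"source": "fitted", "K": K, "alpha": model.alpha,
                          "heldout_score": model.heldout_score,
                          "selection": "k-fold document-completion held-out "
                                       "log-likelihood (LOOCV approximation)"}
        vio.write_profile_table(table, out / "profile_table.tsv")
        profiles = table_to_profiles(table)
        logger.info("stage %s: %d profiled words, K=%d", stage, len(profiles), K)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: scoring + clusters ------------------------------------
    stage = "scoring"
    try:
        cluster_cfg = ClusterConfig(K=K)
        scored_by_subject = {}
        for t in transcripts:
            scored = score_transcript(t, lexicon, profiles)
            clusters = identify_clusters(scored, cluster_cfg)
            scored_by_subject[t.subject_id] = (t.group, scored, clusters)
        vio.write_scored(scored_by_subject, out / "scored.tsv")
        logger.info("stage %s: scored %d transcripts (threshold %.5f)",
                    stage, len(scored_by_subject), cluster_cfg.threshold)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: time course -------------------------------------------
    stage = "time_course"
    try:
        phase_rows, interval_rows = [], []
        for subject, (group, scored, _) in scored_by_subject.items():
            ps = phase_summary(scored)
            for p in range(4):
                phase_rows.append({
                    "subject_id": subject, "group": group, "phase": p + 1,
                    "total_responses": int(ps.total_responses[p]),
                    "n_intrusions": int(ps.n_intrusions[p]),
                    "n_perseverations": int(ps.n_perseverations[p]),
                })
            for mode in INTERVAL_MODES:
                for iv in error_intervals(scored, mode):
                    interval_rows.append({
                        "subject_id": subject, "group": group, "mode": mode,
                        "start_onset": iv.start_onset, "end_onset": iv.end_onset,
                        "gap": iv.gap,
                        "n_intervening_correct": iv.n_intervening_correct,
                    })
        phases = pd.DataFrame(phase_rows)
        intervals = pd.DataFrame(
            interval_rows, columns=["subject_id", "group", "mode", "start_onset",
                                    "end_onset", "gap", "n_intervening_correct"])
        phases.to_csv(out / "phase_summary.tsv", sep="\t", index=False)
        intervals.to_csv(out / "intervals.tsv", sep="\t", index=False)
        logger.info("stage %s: %d phase rows, %d intervals",
                    stage, len(phases), len(intervals))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: statistics --------------------------------------------
    stage = "statistics"
    try:
        stats_rows = []
        per_subject = []
        for subject, (group, scored, clusters) in scored_by_subject.items():
            n_corr = sum(1 for r in scored if r.label == "correct")
            n_pers = sum(1 for r in scored if r.label == PERSEVERATION)
            n_intr = sum(1 for r in scored if r.label in (INTRUSION, NONWORD))
            per_subject.append({"subject_id": subject, "group": group,
                                "n_correct": n_corr, "n_perseverations": n_pers,
                                "n_intrusions": n_intr,
                                "total_errors": n_pers + n_intr})
        subj = pd.DataFrame(per_subject)
        subj.to_csv(out / "subject_summary.tsv", sep="\t", index=False)
        groups = sorted(subj["group"].unique())

        for dv in ("n_correct", "n_perseverations", "n_intrusions"):
            by_group = {g: subj.loc[subj.group == g, dv].to_numpy()
                        for g in groups}
            if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
                res, holm = oneway_anova(by_group)
                stats_rows.append({"analysis": f"oneway_{dv}", "effect": "group",
                                   "statistic": res.F, "df1": res.df_effect,
                                   "df2": res.df_error, "p": res.p,
                                   "effect_size": res.partial_eta_sq})
                holm.to_csv(out / f"holm_{dv}.tsv", sep="\t", index=False)

        long = phases.rename(columns={"total_responses": "value"})[
            ["subject_id", "group", "phase", "value"]]
        if len(groups) >= 2:
            for res in mixed_anova(long, dv="value", subject="subject_id"):
                stats_rows.append({"analysis": "mixed_total_responses",
                                   "effect": res.effect, "statistic": res.F,
                                   "df1": res.df_effect, "df2": res.df_error,
                                   "p": res.p, "effect_size": res.partial_eta_sq})

        # error type x phase chi-square per group, where the table is valid
        for g in groups:
            gp = phases[phases.group == g]
            tab = np.array([gp.groupby("phase")["n_intrusions"].sum().to_numpy(),
                            gp.groupby("phase")["n_perseverations"].sum().to_numpy()])
            try:
                res = chisq_independence(tab)
                stats_rows.append({"analysis": f"chisq_errors_by_phase_{g}",
                                   "effect": "error_type x phase",
                                   "statistic": res.chi2, "df1": res.df,
                                   "df2": 0, "p": res.p, "effect_size": res.w})
            except ValueError:
                logger.info("chi-square for group %s skipped (degenerate table)", g)

        # summed topic probabilities and error-topic correlations per group
        corr_rows = []
        for g in groups:
            items = [v for v in scored_by_subject.values() if v[0] == g]
            all_scored = [r for _, s, _ in items for r in s]
            model_sum = summed_topic_probabilities(all_scored, K, f"{g}:all")
            for label, keep in ((PERSEVERATION, {PERSEVERATION}),
                                (INTRUSION, {INTRUSION, NONWORD})):
                err = [r for r in all_scored if r.label in keep]
                err_sum = summed_topic_probabilities(err, K, f"{g}:{label}")
                r = error_topic_correlation(err_sum, model_sum)
                corr_rows.append({"group": g, "error_type": label,
                                  "n_errors_profiled": err_sum.n_profiled,
                                  "r": np.nan if r is None else r})
        pd.DataFrame(corr_rows).to_csv(out / "error_topic_correlations.tsv",
                                       sep="\t", index=False)

        # within-cluster error shares per group
        share_rows = []
        for g in groups:
            items = [v for v in scored_by_subject.values() if v[0] == g]
            pers_in = intr_in = pers_n = intr_n = 0
            for _, scored, clusters in items:
                in_cluster = {i for c in clusters for i in c.member_indices}
                for r in scored:
                    if r.label == PERSEVERATION:
                        pers_n += 1
                        pers_in += r.index in in_cluster
                    elif r.label in (INTRUSION, NONWORD):
                        intr_n += 1
                        intr_in += r.index in in_cluster
            share_rows.append({
                "group": g,
                "perseveration_share": pers_in / pers_n if pers_n else np.nan,
                "n_perseverations": pers_n,
                "intrusion_share": intr_in / intr_n if intr_n else np.nan,
                "n_intrusions": intr_n,
            })
        pd.DataFrame(share_rows).to_csv(out / "within_cluster_shares.tsv",
                                        sep="\t", index=False)

        # median split of the older-style groups
        split_rows = []
        for g in groups:
            totals = dict(zip(subj.loc[subj.group == g, "subject_id"],
                              subj.loc[subj.group == g, "total_errors"]))
            if totals:
                sg = median_split(totals, g)
                for s, a in sg.assignments.items():
                    split_rows.append({"subject_id": s, "group": g,
                                       "median_cutoff": sg.median_cutoff,
                                       "subgroup": a})
        pd.DataFrame(split_rows).to_csv(out / "subgroups.tsv", sep="\t",
                                        index=False)

        stats = pd.DataFrame(stats_rows)
        stats.to_csv(out / "stats.tsv", sep="\t", index=False)
        logger.info("stage %s: %d statistics rows", stage, len(stats))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- metadata -------------------------------------------------------
    meta = {
        "config": asdict(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "model": model_meta,
        "python": platform.python_version(),
        "n_transcripts": len(transcripts),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1),
                                           encoding="utf-8")
    return {
        "transcripts": transcripts,
        "profiles": profiles,
        "K": K,
        "scored_by_subject": scored_by_subject,
        "phase_summary": phases,
        "intervals": intervals,
        "stats": stats,
        "subject_summary": subj,
    }
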