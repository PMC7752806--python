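"""End-to-end orchestration: simulate -> detect -> score -> analyze.

``run_study`` composes the study stages in order and returns (optionally
writes) every intermediate artifact: the cohort and its questionnaire
scores, per-trial detection results, the learning matrix, the Week-1
(2 x 2 x 6) and Week-2 (2 x 2 x 3) mixed ANCOVAs with post-hoc simple
comparisons, and the two clustering passes (all blocks with majority-rule
k; Week-2 blocks with a three-group solution specified).  A manifest with
the seed, configuration hash and per-stage counts makes a run reproducible
from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as det
from . import score as sco
from . import stats as sta
from . import subtype as sub
from .protocol import StimulusConfig, Week, write_schedule_csv
from .questionnaires import score_cohort
from .synthdata import (
    DEFAULT_PROFILES,
    NoiseParams,
    StudyData,
    sample_cohort,
    simulate_study,
)

log = logging.getLogger("blinkcr")

__all__ = ["RunConfig", "StudyArtifacts", "run_study"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run description; a run is reproducible from this."""

    seed: int = 0
    n_subjects: int = 54
    # (ptsd, mtbi) -> proportion; None = the published 8/21/12/13 split
    composition: tuple | None = None
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    detection: det.DetectionConfig = field(default_factory=det.DetectionConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    gg_policy: str = "mauchly"
    cluster_inputs: str = "all"
    k_range: tuple[int, int] = (2, 8)
    block_size: int = 10
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyArtifacts:
    config: RunConfig
    cohort: pd.DataFrame
    scored: pd.DataFrame
    trial_results: pd.DataFrame
    learning: pd.DataFrame
    excluded: list[dict]
    ancova_week1: sta.RmAncovaResult
    ancova_week2: sta.RmAncovaResult
    posthoc: dict
    subtype_all: sub.ClusterSolution
    subtype_all_report: dict | None
    subtype_week2: sub.ClusterSolution
    subtype_week2_report: dict | None
    manifest: dict


def _detect_study(study: StudyData, config: RunConfig):
    """Run the detector over every simulated session."""
    results_by_subject: dict[str, dict[Week, list]] = {}
    frames = []
    for (sid, week), traces in study.traces.items():
        sched = study.schedules[(sid, week)]
        res = det.classify_session(
            traces,
            list(sched.trials),
            config.detection,
            sample_rate=config.stimulus.sample_rate,
            prefiltered=(study.noise.mode == "envelope"),
        )
        acq = [r for r in res if r.trial.has_cs]
        results_by_subject.setdefault(sid, {})[week] = acq
        frames.append(det.results_to_frame(res, subject_id=sid, week=int(week)))
    trial_results = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    return results_by_subject, trial_results


def run_study(config: RunConfig) -> StudyArtifacts:
    """Execute the whole pipeline for one seed (see module docstring)."""
    stage = "simulate"
    try:
        composition = (
            {(bool(p), bool(m)): w for p, m, w in config.composition}
            if config.composition is not None
            else None
        )
        cohort = sample_cohort(
            n=config.n_subjects, composition=composition, seed=config.seed
        )
        study = simulate_study(
            cohort,
            config=config.stimulus,
            noise=config.noise,
            seed=config.seed,
            block_size=config.block_size,
        )
        log.info("simulate: %d subjects, %d sessions", len(cohort), len(study.schedules))

        stage = "detect"
        results_by_subject, trial_results = _detect_study(study, config)
        n_cr = int(trial_results["cr_present"].sum())
        log.info("detect: %d trials scored, %d CRs", len(trial_results), n_cr)

        stage = "score"
        learning, excluded = sco.assemble_learning_matrix(
            results_by_subject, config.block_size
        )
        log.info("score: %d subjects, %d excluded", len(learning), len(excluded))

        stage = "questionnaires"
        cohort_df = pd.DataFrame()
        from .synthdata import cohort_to_frame

        cohort_df = cohort_to_frame(cohort)
        scored = score_cohort(cohort)

        stage = "stats"
        meta = scored.set_index("subject_id").loc[learning.index]
        w1 = learning[[f"w1b{i}" for i in range(1, 7)]].to_numpy(float)
        w2 = learning[[f"w2b{i}" for i in range(1, 4)]].to_numpy(float)
        ptsd = meta["ptsd_positive"].to_numpy(bool)
        mtbi = meta["mtbi_positive"].to_numpy(bool)
        age = meta["age"].to_numpy(float)
        anc1 = sta.mixed_rm_ancova(w1, ptsd, mtbi, age, gg_policy=config.gg_policy)
        anc2 = sta.mixed_rm_ancova(w2, ptsd, mtbi, age, gg_policy=config.gg_policy)
        posthoc = _posthoc_simple_effects(w2, ptsd, mtbi)

        stage = "subtype"
        k_range = range(config.k_range[0], config.k_range[1] + 1)
        sol_all, rep_all = sub.run_subtype(learning, scored, "all", k_range)
        sol_w2, rep_w2 = sub.run_subtype(learning, scored, "week2", k_range)

        manifest = {
            "seed": config.seed,
            "config_digest": config.digest(),
            "n_subjects": len(cohort),
            "n_trials_scored": int(len(trial_results)),
            "n_crs_detected": n_cr,
            "n_subjects_excluded": len(excluded),
            "ancova_designs": ["2x2x6 (Week 1)", "2x2x3 (Week 2)"],
            "subtype_k_all": int(sol_all.k),
            "subtype_k_week2": int(sol_w2.k),
        }
    except Exception as err:  # annotate which stage failed
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    artifacts = StudyArtifacts(
        config=config,
        cohort=cohort_df,
        scored=scored,
        trial_results=trial_results,
        learning=learning,
        excluded=excluded,
        ancova_week1=anc1,
        ancova_week2=anc2,
        posthoc=posthoc,
        subtype_all=sol_all,
        subtype_all_report=rep_all,
        subtype_week2=sol_w2,
        subtype_week2_report=rep_w2,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_artifacts(artifacts, Path(config.outdir))
    return artifacts


def _posthoc_simple_effects(w2: np.ndarray, ptsd: np.ndarray, mtbi: np.ndarray) -> dict:
    """Simple-effect t-tests of PTSD within each mTBI stratum on Week-2 CR%
    (pooled-variance t, Bonferroni over the two comparisons)."""
    mean_cr = w2.mean(axis=1)
    out = {}
    raw_ps = []
    for level in (True, False):
        sel = mtbi == level
        x = mean_cr[sel & ptsd]
        y = mean_cr[sel & ~ptsd]
        t, df, p = sta.two_sample_t(x, y)
        out[f"ptsd_within_mtbi_{'pos' if level else 'neg'}"] = {
            "t": t, "df": df, "p": p,
            "mean_ptsd_pos": float(x.mean()), "mean_ptsd_neg": float(y.mean()),
        }
        raw_ps.append(p)
    adj = sta.bonferroni_adjust(raw_ps)
    for key, p_adj in zip(out, adj):
        out[key]["p_bonferroni"] = p_adj
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_artifacts(a: StudyArtifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    a.cohort.to_csv(outdir / "cohort.csv", index=False)
    a.scored.to_csv(outdir / "scored_subjects.csv", index=False)
    a.trial_results.to_csv(outdir / "trial_results.csv", index=False)
    a.learning.to_csv(outdir / "learning_series.csv")
    effects = {
        "week1": json.loads(a.ancova_week1.table.to_json(orient="index")),
        "week2": json.loads(a.ancova_week2.table.to_json(orient="index")),
        "posthoc": a.posthoc,
    }
    (outdir / "ancova.json").write_text(json.dumps(effects, indent=2, default=_jsonable))
    (outdir / "ancova.txt").write_text(
        "Week 1 (2x2x6)\n" + a.ancova_week1.to_text()
        + "\n\nWeek 2 (2x2x3)\n" + a.ancova_week2.to_text() + "\n"
    )
    for tag, sol, rep in (
        ("all", a.subtype_all, a.subtype_all_report),
        ("week2", a.subtype_week2, a.subtype_week2_report),
    ):
        pd.DataFrame(
            {"subject_id": sol.subject_ids, "cluster": sol.labels,
             "profile": [sol.profile_names[c] for c in sol.labels]}
        ).to_csv(outdir / f"subtype_{tag}_labels.csv", index=False)
        (outdir / f"subtype_{tag}_votes.json").write_text(
            json.dumps({"k": sol.k, "votes": sol.index_votes}, indent=2)
        )
        (outdir / f"subtype_{tag}_tree.json").write_text(
            json.dumps(sol.merge_tree.tolist())
        )
        if rep is not None:
            (outdir / f"subtype_{tag}_report.json").write_text(
                json.dumps(rep, indent=2, default=_jsonable)
            )
    (outdir / "manifest.json").write_text(json.dumps(a.manifest, indent=2))
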