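"""End-to-end analysis pipeline: QC -> scoring -> validation -> associations.

Stages mirror the study's analysis plan: screen invalid responders and
score outliers, score all scales, then run the validation analyses in order
(item informativeness, test-retest reliability, convergent validity
against the MCQ, random-subset abbreviation, adjusted outcome
regressions).  Every artifact directory is stamped with a config hash and
the seed so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import associations, psychometrics, qc, scoring, simulate
from .io import read_responses, read_table, write_table
from .items import ItemBank, default_banks, load_bank

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("delaykit")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; either file paths or a simulator preset."""

    # inputs: either paths ...
    responses_path: str | None = None
    followups_path: str | None = None  # per-survey binary endorsements
    covariates_path: str | None = None
    bank_paths: dict = field(default_factory=dict)  # scale -> YAML path
    # ... or a simulation preset ("clean" | "contaminated" | "null")
    simulate_preset: str | None = None
    n_participants: int | None = None

    # QC options
    qc_threshold: float = 3.0
    qc_on: str = "log_k"  # standardize log_k (default) or k_geomean
    min_delay_days: float = 1.0

    # psychometrics options
    informative_cutoff: float = 0.5
    abbreviation_iterations: int = 100
    abbreviation_full_scale: str = "informative"  # or "all"

    seed: int = 0
    out_dir: str = "delaykit_output"
    write_plots: bool = False


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    scores: pd.DataFrame
    item_k: pd.DataFrame
    qc_result: qc.QcResult
    item_total: dict  # (scale, phase) -> frame
    informative_items: dict  # scale -> list of item ids
    test_retest: dict  # scale -> CorrelationResult
    convergent_r: pd.DataFrame
    convergent_p: pd.DataFrame
    abbreviation: dict  # scale -> summary frame
    regressions: pd.DataFrame | None
    config_hash: str


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in vars(cfg).items() if k != "out_dir"},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    banks = default_banks()
    for scale, path in cfg.bank_paths.items():
        banks[scale] = load_bank(path)
    if cfg.simulate_preset is not None:
        preset = {
            "clean": simulate.clean_config,
            "contaminated": simulate.contaminated_config,
            "null": simulate.null_config,
        }[cfg.simulate_preset]
        overrides = {"seed": cfg.seed}
        if cfg.n_participants is not None:
            overrides["n_participants"] = cfg.n_participants
        study = simulate.simulate_study(preset(**overrides))
        return study.responses, study.followup_surveys, study.covariates, banks
    if cfg.responses_path is None:
        raise ValueError("either responses_path or simulate_preset is required")
    responses = read_responses(cfg.responses_path, banks)
    followups = read_table(cfg.followups_path) if cfg.followups_path else None
    covariates = read_table(cfg.covariates_path) if cfg.covariates_path else None
    return responses, followups, covariates, banks


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages, writing delimited artifacts to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        responses, followups, covariates, banks = _load_inputs(cfg)

        stage("score")
        item_k, scores = scoring.score_study(
            responses, banks, min_delay_days=cfg.min_delay_days
        )

        stage("qc")
        qc_result = qc.run_qc(
            responses, banks, scores,
            threshold=cfg.qc_threshold, on=cfg.qc_on,
            min_delay_days=cfg.min_delay_days,
        )
        analytic = qc_result.analytic_sample
        log.info("analytic sample: %d of %d participants",
                 len(analytic), len(qc_result.all_participants))

        stage("item_informativeness")
        item_total, informative = {}, {}
        for scale in ("time", "monetary"):
            for phase in ("phase1", "phase2_baseline"):
                tab = psychometrics.item_total_correlations(
                    item_k, scale, phase,
                    participants=analytic, cutoff=cfg.informative_cutoff,
                )
                item_total[(scale, phase)] = tab
            p1 = item_total[(scale, "phase1")]
            informative[scale] = sorted(p1.loc[p1["informative"], "item_id"])

        stage("test_retest")
        retest = {
            scale: psychometrics.test_retest(scores, scale, participants=analytic)
            for scale in ("time", "monetary")
        }

        stage("convergent_validity")
        scales = ["mcq", "time", "monetary"] if "mcq" in banks else ["time", "monetary"]
        conv_r, conv_p, _ = psychometrics.convergent_validity(
            scores, scales=scales, participants=analytic
        )

        stage("abbreviation")
        abbreviation = {}
        for scale in ("time", "monetary"):
            items = informative[scale]
            if len(items) < 2:
                continue
            full = banks[scale].item_ids if cfg.abbreviation_full_scale == "all" else items
            draws = psychometrics.abbreviation_analysis(
                item_k, scale, "phase1",
                items=items, full_items=full,
                iterations=cfg.abbreviation_iterations,
                seed=cfg.seed, participants=analytic,
            )
            abbreviation[scale] = psychometrics.abbreviation_summary(draws)

        stage("associations")
        regressions = None
        if followups is not None and covariates is not None and len(followups):
            outcomes = associations.endorsement_percentages(followups)
            regressions = associations.fit_adjusted_models(
                outcomes, scores, covariates,
                scales=scales, participants=analytic,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    stage("write")
    stamp = {"config_hash": chash, "seed": cfg.seed}
    (out / "run_info.json").write_text(json.dumps(stamp, indent=2))
    write_table(scores, out / "scores.csv")
    write_table(qc_result.decisions, out / "qc_decisions.csv")
    (out / "qc_summary.txt").write_text(qc_result.summary() + "\n")
    for (scale, phase), tab in item_total.items():
        write_table(tab, out / f"item_total_{scale}_{phase}.csv")
    retest_tab = pd.DataFrame(
        [{"scale": s, "r": c.r, "p": c.p, "n": c.n} for s, c in retest.items()]
    )
    write_table(retest_tab, out / "test_retest.csv")
    conv_r.to_csv(out / "convergent_validity_r.csv")
    conv_p.to_csv(out / "convergent_validity_p.csv")
    for scale, tab in abbreviation.items():
        write_table(tab, out / f"abbreviation_{scale}.csv")
    if regressions is not None:
        write_table(regressions, out / "associations.csv")
    if cfg.write_plots:
        from . import plots
        for scale, tab in abbreviation.items():
            plots.abbreviation_curve(tab, out / f"abbreviation_{scale}.png")

    return PipelineResult(
        scores=scores, item_k=item_k, qc_result=qc_result,
        item_total=item_total, informative_items=informative,
        test_retest=retest, convergent_r=conv_r, convergent_p=conv_p,
        abbreviation=abbreviation, regressions=regressions,
        config_hash=chash,
    )
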