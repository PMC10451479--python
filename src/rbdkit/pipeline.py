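"""End-to-end pipeline: simulate -> score -> classify -> outcomes -> report.

Each stage is a pure function of the configuration and seed; any stage
failure aborts the run with a stage-labelled error.  The report bundle
contains five artifacts: the per-subject-block score table, the
classification table, the subgroup comparison report, the moderation-test
summary, and a run log with seeds, sizes, parameter hash, and versions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__, classifier, cohort, outcomes, rbd, sdt
from .io import PipelineConfig, ensure_outdir, write_trials, write_visits

log = logging.getLogger("rbdkit")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def score_sessions(sessions, payoff: rbd.PayoffStructure,
                   method_tag: str = "ev_shortfall") -> pd.DataFrame:
    """Per subject-block table of classical SDT measures and RBD."""
    rows = []
    for s in sessions:
        for counts in sdt.tabulate_blocks(s):
            m = sdt.sdt_measures(counts)
            score = rbd.compute_rbd(counts, payoff, method_tag=method_tag)
            rows.append({
                "subject_id": s.subject_id, "group": s.group, "block": counts.block,
                "log_b": m.log_b, "log_d": m.log_d,
                "correction_applied": int(m.correction_applied),
                "rewards_delivered": counts.rewards_delivered,
                "rbd": score.rbd, "method_tag": score.method_tag,
                "d_prime_hat": score.d_prime_hat,
                "criterion_hat": score.criterion_hat,
            })
    return pd.DataFrame(rows)


def classify_cohort(scores: pd.DataFrame, priors=None):
    """Fit the block-2 QDA cutoff on MDD vs HC and label the MDD subjects.

    Returns ``(model, classification table)``; every subject gets a label,
    but the cutoff is derived only from the block-2 scores of both groups.
    """
    b2 = scores[scores["block"] == 2]
    mdd = b2.loc[b2["group"] == "MDD", "rbd"]
    hc = b2.loc[b2["group"] == "HC", "rbd"]
    model = classifier.fit_qda_1d(mdd.to_numpy(), hc.to_numpy(), priors=priors)
    table = b2[["subject_id", "group", "rbd"]].rename(
        columns={"rbd": "block2_rbd"}).copy()
    table["label"] = classifier.classify(table["block2_rbd"].to_numpy(), model)
    table["cutoff"] = model.cutoff
    return model, table.reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline, writing all artifacts to ``config.out_dir``."""
    out = ensure_outdir(config)
    report: dict = {}

    try:
        sessions, demographics = cohort.simulate_cohort(config.cohort)
        seeds = np.random.SeedSequence(config.rng_seed).spawn(2)
        visits = cohort.simulate_outcomes(demographics,
                                          config.cohort.outcome_params,
                                          seeds[0])
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    write_trials(sessions, out / "trials.csv")
    demographics.to_csv(out / "demographics.csv", index=False)
    write_visits(visits, out / "visits.csv")

    try:
        payoff = config.cohort.schedule.payoff()
        scores = score_sessions(sessions, payoff, method_tag=config.rbd_method)
    except Exception as exc:
        raise StageError("score", exc) from exc
    scores.to_csv(out / "scores.csv", index=False)
    report["scores"] = scores

    try:
        model, classification = classify_cohort(scores, priors=config.qda_priors)
    except Exception as exc:
        raise StageError("classify", exc) from exc
    for k, v in (("cutoff", model.cutoff), ("mean_hc", model.mean_hc),
                 ("sd_hc", model.sd_hc), ("mean_mdd", model.mean_mdd),
                 ("sd_mdd", model.sd_mdd)):
        classification[k] = v
    classification.to_csv(out / "classification.csv", index=False)
    report["model"] = model
    report["classification"] = classification

    try:
        mdd_mask = classification["group"] == "MDD"
        mdd_class = classification[mdd_mask].set_index("subject_id")
        demo_mdd = demographics[demographics["group"] == "MDD"]
        labels_mdd = mdd_class.loc[demo_mdd["subject_id"], "label"].tolist()
        comparisons = classifier.compare_groups(demo_mdd, labels_mdd)
        comparison = classifier.comparison_table(comparisons)
        diag = classifier.diagnostic_stats(
            classification["label"].tolist(), classification["group"].tolist())
    except Exception as exc:
        raise StageError("compare", exc) from exc
    comparison.to_csv(out / "group_comparison.csv", index=False)
    report["comparison"] = comparison
    report["diagnostics"] = diag

    try:
        labels = dict(zip(classification["subject_id"], classification["label"]))
        result = outcomes.fit_moderation_model(
            outcomes.visits_to_frame(visits), labels,
            spec=outcomes.ModelSpec(df_method=config.df_method))
        moderation = pd.DataFrame({
            "estimate": result.params, "se": result.bse})
        moderation.index.name = "term"
    except Exception as exc:
        raise StageError("outcomes", exc) from exc
    moderation.to_csv(out / "moderation_coefficients.csv")
    summary = {
        "interaction_stat": result.interaction_stat,
        "interaction_df": list(result.interaction_df),
        "interaction_p": result.interaction_p,
        "sigma_resid": result.sigma_resid,
        "sigma_intercept": result.sigma_intercept,
        "rho": result.rho,
        "n_obs": result.n_obs,
        "n_subjects": result.n_subjects,
    }
    with open(out / "moderation_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    report["moderation"] = result

    run_log = {
        "seed": config.rng_seed,
        "n_mdd": int(config.cohort.n_mdd),
        "n_hc": int(config.cohort.n_hc),
        "n_sessions": len(sessions),
        "n_visits": len(visits),
        "config_hash": cohort.config_hash(config.cohort),
        "rbd_method": config.rbd_method,
        "rbdkit_version": __version__,
        "python": platform.python_version(),
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    report["run_log"] = run_log
    log.info("pipeline complete: seed=%s n=%s hash=%s", config.rng_seed,
             len(sessions), run_log["config_hash"])
    return report
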