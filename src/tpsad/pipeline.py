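"""End-to-end report: simulate a cohort, filter, deconvolve PSA, compare
groups, run quintile Kaplan–Meier + log-rank and multivariable Cox, the
expression meta-analysis, and the IHC optical-density comparison.

Every table written carries the configuration hash and seed; identical
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import apply_cohort_filters, compute_tpsad_cohort
from .expression import geneset_direction_summary, meta_analysis, meta_results_frame
from .ihc import sample_region_ods
from .io import RunConfig, write_cohort_csv, write_table
from .simulate import simulate_cohort, simulate_expression_studies, simulate_ihc_image
from .survival import (
    CoxFit,
    SurvivalData,
    cox_fit,
    group_compare,
    km_curve,
    logrank_test,
    quintile_strata,
)

logger = logging.getLogger("tpsad")

GRADE_DUMMIES = ["grade_intermediate", "grade_high"]
COX_COVARIATES = ["epe", "svi", "positive_margins"] + GRADE_DUMMIES


def cox_design(cohort: pd.DataFrame, extra: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Design matrix of the multivariable recurrence model.

    Binary adverse features plus treatment-coded grade dummies (low grade is
    the reference); ``extra`` columns (e.g. ln tPSAD) are appended.
    """
    design = pd.DataFrame(
        {
            "epe": cohort["epe"].astype(float).to_numpy(),
            "svi": cohort["svi"].astype(float).to_numpy(),
            "positive_margins": cohort["positive_margins"].astype(float).to_numpy(),
            "grade_intermediate": (cohort["grade_group"] == "intermediate").astype(float).to_numpy(),
            "grade_high": (cohort["grade_group"] == "high").astype(float).to_numpy(),
        },
        index=cohort.index,
    )
    if extra is not None:
        design = design.join(extra)
    return design


def fit_recurrence_cox(
    cohort: pd.DataFrame, extra: Optional[pd.DataFrame] = None
) -> CoxFit:
    """Multivariable Cox fit of biochemical recurrence on a cohort table."""
    design = cox_design(cohort, extra)
    data = SurvivalData(
        times=cohort["followup_time"].to_numpy(float),
        events=cohort["recurrence"].to_numpy(bool),
        covariates=design,
    )
    return cox_fit(data)


@dataclass
class RunReport:
    """Paths and headline numbers of one end-to-end run."""

    out_dir: Path
    n_simulated: int
    n_kept: int
    exclusions: pd.DataFrame
    group_comparisons: pd.DataFrame
    logrank: tuple
    cox: pd.DataFrame
    meta: pd.DataFrame
    meta_counts: tuple
    ihc: pd.DataFrame


def _plot_km_quintiles(km_frames, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for frame in km_frames:
        q = int(frame["quintile"].iloc[0])
        t = np.concatenate([[0.0], frame["time"].to_numpy()])
        s = np.concatenate([[1.0], frame["survival"].to_numpy()])
        ax.step(t, s, where="post", label=f"Q{q}")
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title="ln(tPSAD) quintile", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stamp(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    table = table.copy()
    table.insert(0, "config_hash", config.config_hash())
    table.insert(1, "seed", config.seed)
    return table


def run_full_pipeline(config: RunConfig | None = None) -> RunReport:
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    try:
        logger.info(
            "tpsad %s | python %s | config %s | seed %d",
            __version__, platform.python_version(), config.config_hash(), config.seed,
        )

        # --- simulate + filter + deconvolve -------------------------------
        stage = "simulate"
        cohort = simulate_cohort(config.cohort_sim, seed=seeds[0])
        write_cohort_csv(cohort, out / "cohort.csv")

        stage = "filter"
        kept, exclusions = apply_cohort_filters(cohort, config.constants)
        for rule, n, _ in exclusions.rules:
            logger.info("excluded %d cases: %s", n, rule)
        write_table(_stamp(exclusions.as_frame(), config), out / "exclusions.tsv")

        stage = "tpsad"
        results = compute_tpsad_cohort(kept, config.constants, config.volume_field)
        results = results.set_index(kept.index)
        write_table(_stamp(results, config), out / "tpsad.tsv")

        # --- group comparisons (log scale) --------------------------------
        stage = "group comparisons"
        loggable = results["valid_for_log"].to_numpy()
        ln_vals = results.loc[loggable, "ln_tpsad"].to_numpy()
        sub = kept.loc[loggable]
        rows = []
        stat, p = group_compare(ln_vals, sub["grade_group"], test="anova")
        rows.append(("ln_tpsad_by_grade", "anova", stat, p))
        stat, p = group_compare(ln_vals, sub["stage"], test="ttest")
        rows.append(("ln_tpsad_by_stage", "ttest", stat, p))
        stat, p = group_compare(ln_vals, sub["recurrence"], test="ttest")
        rows.append(("ln_tpsad_by_recurrence", "ttest", stat, p))
        comparisons = pd.DataFrame(rows, columns=["comparison", "test", "statistic", "p"])
        write_table(_stamp(comparisons, config), out / "group_comparisons.tsv")

        # --- quintile KM + log-rank ---------------------------------------
        stage = "survival"
        strata = quintile_strata(ln_vals)
        surv = SurvivalData(
            times=sub["followup_time"].to_numpy(float),
            events=sub["recurrence"].to_numpy(bool),
        )
        km_rows = []
        for q in sorted(np.unique(strata)):
            mask = strata == q
            curve = km_curve(SurvivalData(surv.times[mask], surv.events[mask]))
            frame = curve.as_frame()
            frame.insert(0, "quintile", q)
            km_rows.append(frame)
        write_table(_stamp(pd.concat(km_rows, ignore_index=True), config), out / "km_quintiles.tsv")
        _plot_km_quintiles(km_rows, out / "km_quintiles.png")
        logrank = logrank_test(surv, strata)
        logger.info("log-rank over tPSAD quintiles: chi2=%.3f df=%d p=%.2e", *logrank)

        stage = "cox"
        fit = fit_recurrence_cox(
            sub, extra=pd.DataFrame({"ln_tpsad": ln_vals}, index=sub.index)
        )
        cox_table = fit.summary().rename_axis("covariate").reset_index()
        cox_table["converged"] = fit.converged
        write_table(_stamp(cox_table, config), out / "cox.tsv")

        # --- expression meta-analysis -------------------------------------
        stage = "meta-analysis"
        studies = simulate_expression_studies(config.expression_sim, seed=seeds[1])
        geneset = config.expression_sim.cassette_genes + ["AR"]
        meta = meta_analysis(studies, geneset, n_perm=config.n_perm, seed=seeds[2])
        meta_frame = meta_results_frame(meta)
        write_table(_stamp(meta_frame, config), out / "meta.tsv")
        counts = geneset_direction_summary(
            [r for r in meta if r.gene != "AR"], alpha=config.alpha
        )
        logger.info(
            "gene set: %d/%d down-significant, %d up-significant at alpha=%g",
            counts[0], counts[2], counts[1], config.alpha,
        )

        # --- IHC optical density ------------------------------------------
        stage = "ihc"
        rng = np.random.default_rng(seeds[3])
        ihc_rows = []
        for group, od in (("low_grade", config.ihc_low_od), ("high_grade", config.ihc_high_od)):
            for i in range(config.ihc_images_per_group):
                img = simulate_ihc_image(od, seed=int(rng.integers(2**31)))
                ods, mean_od, _ = sample_region_ods(
                    img, region_size=config.ihc_region_size,
                    seed=int(rng.integers(2**31)),
                )
                ihc_rows.append((group, i, *ods, mean_od))
        ihc = pd.DataFrame(
            ihc_rows, columns=["group", "image", "od_1", "od_2", "od_3", "mean_od"]
        )
        stat, p = group_compare(ihc["mean_od"], ihc["group"], test="ttest")
        logger.info("IHC OD low vs high grade: t=%.3f p=%.2e", stat, p)
        write_table(_stamp(ihc, config), out / "ihc.tsv")

        # --- run log -------------------------------------------------------
        run_meta = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_simulated": int(len(cohort)),
            "n_kept": int(len(kept)),
            "exclusions": {rule: int(n) for rule, n, _ in exclusions.rules},
            "logrank": {"chi2": logrank[0], "df": logrank[1], "p": logrank[2]},
            "geneset_counts": {
                "n_down_significant": counts[0],
                "n_up_significant": counts[1],
                "n_total": counts[2],
            },
            "ihc_ttest": {"t": stat, "p": p},
        }
        (out / "run_log.yaml").write_text(yaml.safe_dump(run_meta, sort_keys=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunReport(
        out_dir=out,
        n_simulated=len(cohort),
        n_kept=len(kept),
        exclusions=exclusions.as_frame(),
        group_comparisons=comparisons,
        logrank=logrank,
        cox=cox_table,
        meta=meta_frame,
        meta_counts=counts,
        ihc=ihc,
    )
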