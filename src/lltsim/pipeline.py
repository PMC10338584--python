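"""End-to-end analysis workflow: load, filter, summarise, simulate, export.

``run_pipeline`` is the library entry point behind the ``lltsim report``
command: it reads a cohort file, applies the eligibility waterfall,
summarises the baseline, runs the Monte Carlo intensification study, and
writes a results bundle (JSON plus delimited tables for the waterfall, the
per-step goal-attainment summary and the LDL-C histogram).

Everything written is reproducible from the manifest: a rerun with the same
inputs and master seed produces byte-identical output (no timestamps are
embedded; wall-clock information goes to stderr logging only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    RiskLevel,
    apply_eligibility_filter,
    summarize_baseline,
)
from .efficacy import BetaReduction, EfficacyPoolRule, LognormalRatio
from .errors import EmptyCohortError
from .simulate import (
    MonteCarloSummary,
    PathwayStep,
    RepResult,
    SimulationConfig,
    run_monte_carlo,
    run_replicate,
)

logger = logging.getLogger("lltsim")


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Recognised sections: ``efficacy`` (ezetimibe alpha/beta; per-pool
    log_mean/log_sd) and ``simulation`` (n_reps, master_seed, cutoffs,
    goal_thresholds_mgdl keyed by risk label).  Missing entries fall back to
    the defaults that reproduce the published distributions.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    eff_raw = raw.get("efficacy", {})
    default_rule = EfficacyPoolRule.default()
    eze = eff_raw.get("ezetimibe", {})
    p1 = eff_raw.get("pool_moderate_high", {})
    p2 = eff_raw.get("pool_none_low", {})
    rule = EfficacyPoolRule(
        ezetimibe=BetaReduction(
            alpha=float(eze.get("alpha", default_rule.ezetimibe.alpha)),
            beta=float(eze.get("beta", default_rule.ezetimibe.beta)),
        ),
        pool_moderate_high=LognormalRatio(
            log_mean=float(p1.get("log_mean", default_rule.pool_moderate_high.log_mean)),
            log_sd=float(p1.get("log_sd", default_rule.pool_moderate_high.log_sd)),
        ),
        pool_none_low=LognormalRatio(
            log_mean=float(p2.get("log_mean", default_rule.pool_none_low.log_mean)),
            log_sd=float(p2.get("log_sd", default_rule.pool_none_low.log_sd)),
        ),
    )
    sim_raw = raw.get("simulation", {})
    thresholds_raw = sim_raw.get("goal_thresholds_mgdl", {})
    thresholds = {
        RiskLevel.HIGH: float(thresholds_raw.get("high", 70.0)),
        RiskLevel.VERY_HIGH: float(thresholds_raw.get("very_high", 55.0)),
    }
    return SimulationConfig(
        n_reps=int(sim_raw.get("n_reps", 10_000)),
        master_seed=int(sim_raw.get("master_seed", 0)),
        efficacy=rule,
        goal_thresholds=thresholds,
        cutoffs=tuple(float(c) for c in sim_raw.get("cutoffs", (55.0, 70.0))),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "efficacy": {
            "ezetimibe": {
                "alpha": config.efficacy.ezetimibe.alpha,
                "beta": config.efficacy.ezetimibe.beta,
            },
            "pool_moderate_high": {
                "log_mean": config.efficacy.pool_moderate_high.log_mean,
                "log_sd": config.efficacy.pool_moderate_high.log_sd,
            },
            "pool_none_low": {
                "log_mean": config.efficacy.pool_none_low.log_mean,
                "log_sd": config.efficacy.pool_none_low.log_sd,
            },
        },
        "simulation": {
            "n_reps": config.n_reps,
            "master_seed": config.master_seed,
            "goal_thresholds_mgdl": {
                r.value: t for r, t in config.goal_thresholds.items()
            },
            "cutoffs": list(config.cutoffs),
        },
    }


@dataclass(frozen=True)
class RunManifest:
    """Provenance block sufficient to reproduce a run bit-for-bit."""

    config: dict
    master_seed: int
    software_version: str
    input_digests: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "master_seed": self.master_seed,
            "software_version": self.software_version,
            "input_digests": self.input_digests,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def export_histogram_table(rep: RepResult, bin_width: float) -> pd.DataFrame:
    """Per-step LDL-C histogram with half-open bins [k*w, (k+1)*w).

    Returns a tidy table (step, bin_left, bin_right, count); counts at each
    step sum to the cohort size.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    rows = []
    for step in PathwayStep:
        ldl = rep.ldl[int(step)]
        ks = np.floor(ldl / bin_width).astype(int)
        for k in sorted(set(ks.tolist())):
            rows.append(
                {
                    "step": step.name.lower(),
                    "bin_left": k * bin_width,
                    "bin_right": (k + 1) * bin_width,
                    "count": int((ks == k).sum()),
                }
            )
    return pd.DataFrame(rows, columns=["step", "bin_left", "bin_right", "count"])


def _goal_attainment_table(summary: MonteCarloSummary) -> pd.DataFrame:
    rows = []
    n = summary.n_patients
    for step, s in summary.steps.items():
        rows.append(
            {
                "step": step.name.lower(),
                "at_goal_median": s.at_goal_count.median,
                "at_goal_q025": s.at_goal_count.q025,
                "at_goal_q975": s.at_goal_count.q975,
                "at_goal_pct_median": 100.0 * s.at_goal_count.median / n,
                "mean_ldl_median": s.mean_ldl.median,
                "mean_ldl_q025": s.mean_ldl.q025,
                "mean_ldl_q975": s.mean_ldl.q975,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort_path,
    config_path=None,
    out_dir="results",
    seed: int | None = None,
    n_reps: int | None = None,
    histogram_bin_width: float = 10.0,
    trace_file=None,
) -> dict:
    """Full analysis: load -> filter -> baseline summary -> Monte Carlo -> export.

    ``seed`` and ``n_reps`` override the config file.  Returns the results
    bundle (also written to ``out_dir``): manifest, waterfall, baseline
    summary, Monte Carlo summary, and figure-ready tables.
    """
    cohort_path = Path(cohort_path)
    config = load_config(config_path) if config_path else SimulationConfig()
    if seed is not None or n_reps is not None:
        import dataclasses as _dc

        config = _dc.replace(
            config,
            master_seed=config.master_seed if seed is None else int(seed),
            n_reps=config.n_reps if n_reps is None else int(n_reps),
        )

    raw = Cohort.from_csv(cohort_path, label=cohort_path.stem)
    logger.info("loaded cohort %s: %d patients", cohort_path, len(raw))

    eligible, waterfall = apply_eligibility_filter(raw)
    logger.info(
        "eligibility filter: %s", " -> ".join(str(c) for c in waterfall.stage_counts)
    )
    if len(eligible) == 0:
        raise EmptyCohortError(
            "no patients remain after the eligibility filter; aborting"
        )

    baseline = summarize_baseline(eligible, cutoffs=config.cutoffs,
                                  thresholds=config.goal_thresholds)
    logger.info(
        "baseline: N=%d, mean LDL-C %.2f mg/dL, %d at goal",
        baseline.n, baseline.ldl_mean, baseline.n_at_goal,
    )

    summary = run_monte_carlo(eligible, config, trace_file=trace_file)
    logger.info(
        "Monte Carlo done: %d replicates, master seed %d",
        summary.n_reps, summary.master_seed,
    )

    digests = {cohort_path.name: _sha256(cohort_path)}
    if config_path:
        digests[Path(config_path).name] = _sha256(config_path)
    manifest = RunManifest(
        config=config_to_dict(config),
        master_seed=config.master_seed,
        software_version=__version__,
        input_digests=digests,
    )

    rep0 = run_replicate(eligible, config, 0)
    hist = export_histogram_table(rep0, bin_width=histogram_bin_width)

    bundle = {
        "manifest": manifest.to_dict(),
        "waterfall": {
            "stage": list(waterfall.stage_names),
            "n": list(waterfall.stage_counts),
        },
        "baseline": baseline.to_dict(),
        "monte_carlo": summary.to_dict(),
    }

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    waterfall.to_dataframe().to_csv(out / "waterfall.csv", index=False)
    _goal_attainment_table(summary).to_csv(out / "goal_attainment_by_step.csv",
                                           index=False)
    hist.to_csv(out / "ldl_histogram.csv", index=False)
    logger.info("results written to %s", out)
    return bundle


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[lltsim] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
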