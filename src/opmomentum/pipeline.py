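"""End-to-end run: design -> simulate -> descriptives -> Bayesian fit -> report.

Every intermediate is persisted as CSV/JSON with a pinned dialect (UTF-8,
comma separators, '.' decimals, semicolon-joined list cells) so repeated
runs with the same configuration produce byte-identical tables.
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

from . import bayes, metrics, synthetic
from .synthetic import CUEING_COLUMNS, TRIAL_COLUMNS, GroupParams

logger = logging.getLogger(__name__)

REQUIRED_TRIAL_COLUMNS = TRIAL_COLUMNS


@dataclass
class RunConfig:
    seed: int = 1
    n_per_group: int = synthetic.DEFAULT_N_PER_GROUP
    n_iter: int = 60_000
    burn_in: int = 10_000
    hdi_mass: float = 0.95
    thin: int = 10
    outdir: str = "results/run"
    trials_path: str | None = None  # user-supplied table skips simulation
    cueing_path: str | None = None
    child_overrides: dict = field(default_factory=dict)
    adult_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0 < self.hdi_mass < 1:
            raise ValueError("hdi_mass must lie in (0, 1)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def group_params(self) -> tuple[GroupParams, GroupParams]:
        child = dataclasses.replace(synthetic.CHILD_DEFAULTS, **self.child_overrides)
        adult = dataclasses.replace(synthetic.ADULT_DEFAULTS, **self.adult_overrides)
        return child, adult

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_digest: str
    n_subjects: int
    n_trials: int
    n_cueing_trials: int
    om_difference_mean: dict[str, float]
    posterior: dict[str, dict[str, float]]
    correlations: dict[str, float]
    checks: dict[str, bool]


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    table.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy calculation-trial table.

    An empty file yields an empty table.  Rows whose chosen value is not
    among the displayed alternatives are flagged (with line numbers) but
    kept; downstream metrics reject them per-operation.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=REQUIRED_TRIAL_COLUMNS)
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    arith = table[table["task"] != "cueing"]
    for idx, row in arith.iterrows():
        alts = {int(a) for a in str(row["alternatives"]).split(";")}
        if int(row["chosen"]) not in alts:
            logger.warning(
                "%s line %d: chosen value %s not among alternatives %s",
                path, idx + 2, row["chosen"], sorted(alts),
            )
    return table


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order, persisting all intermediates."""
    config.validate()
    digest = config.digest()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = logger.getChild(digest)
    log.info("seed=%d config=%s starting run", config.seed, digest)

    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)

    # --- stage: simulate (or load) ---
    if config.trials_path:
        trials = read_trials(config.trials_path)
        cueing = (
            pd.read_csv(config.cueing_path)
            if config.cueing_path else pd.DataFrame(columns=CUEING_COLUMNS)
        )
        truth = pd.DataFrame()
        log.info("seed=%d config=%s loaded %d trials", config.seed, digest, len(trials))
    else:
        child, adult = config.group_params()
        trials, cueing, truth = synthetic.simulate_cohort(
            child, adult, config.n_per_group, config.seed
        )
        log.info("seed=%d config=%s simulated %d trials", config.seed, digest, len(trials))
    write_trials(trials, out / "trials.csv")
    cueing.to_csv(out / "cueing.csv", index=False)
    if len(truth):
        truth.to_csv(out / "truth.csv", index=False)

    # --- stage: descriptives ---
    bias = metrics.om_bias(trials)
    cv = metrics.cv_profile(trials)
    ranks = metrics.rank_distribution(trials)
    bias.to_csv(out / "bias.csv", index=False)
    cv.to_csv(out / "cv.csv", index=False)
    ranks.to_csv(out / "ranks.csv", index=False)

    correlations: dict[str, float] = {}
    if len(cueing):
        effects = metrics.cueing_effects(cueing)
        effects.to_csv(out / "cueing_effects.csv", index=False)
        merged = bias.merge(effects, on=["subject_id", "group"])
        if len(merged) >= 3:
            r, p = metrics.correlate(merged["om_difference"], merged["reorienting"])
            correlations["om_reorienting_r"] = r
            correlations["om_reorienting_p"] = p
            r_o, p_o = metrics.correlate(merged["om_difference"], merged["orienting"])
            correlations["om_orienting_r"] = r_o
            correlations["om_orienting_p"] = p_o
    with open(out / "correlations.json", "w", encoding="utf-8") as fh:
        json.dump(correlations, fh, indent=2)
    log.info("seed=%d config=%s descriptives done (%d subjects)",
             config.seed, digest, len(bias))

    # --- stage: Bayesian fit ---
    data = bayes.model_data_from_bias(bias)
    draws = bayes.gibbs_sample(
        data, bayes.Priors(), config.n_iter, config.burn_in, seed=config.seed
    )
    summary = bayes.summarize_posterior(draws, config.hdi_mass)
    draws.to_frame(thin=config.thin).to_csv(out / "draws.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        fh.write(bayes.summary_to_json(summary))
    log.info("seed=%d config=%s sampler done (%d retained draws)",
             config.seed, digest, draws.n_draws)

    # --- stage: report ---
    rank_sums = ranks.groupby(["task", "range_flag"])["proportion"].sum()
    checks = {
        "trial_count_per_subject_44": bool(
            (trials.groupby("subject_id").size() == 44).all()
        ),
        "rank_proportions_sum_to_1": bool(
            np.allclose(rank_sums, 1.0, atol=1e-9)
        ),
        "bias_rows_match_subjects": len(bias) == trials["subject_id"].nunique(),
        "posterior_rows_13": len(summary) == len(bayes.SUMMARY_ROWS),
    }
    om_means = bias.groupby("group")["om_difference"].mean().to_dict()
    posterior = {
        r["quantity"]: {"mean": r["mean"], "hdi_low": r["hdi_low"],
                        "hdi_high": r["hdi_high"], "p_positive": r["p_positive"]}
        for _, r in summary.iterrows()
    }
    report = RunReport(
        config_digest=digest,
        n_subjects=int(trials["subject_id"].nunique()),
        n_trials=int(len(trials)),
        n_cueing_trials=int(len(cueing)),
        om_difference_mean={k: float(v) for k, v in om_means.items()},
        posterior=posterior,
        correlations=correlations,
        checks=checks,
    )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    if not all(checks.values()):
        log.warning("seed=%d config=%s invariant checks failed: %s",
                    config.seed, digest,
                    [k for k, v in checks.items() if not v])
    return report
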