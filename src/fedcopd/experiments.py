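"""End-to-end experiment drivers: federated-vs-isolated comparison, sweeps
over sample size / communication rounds / split ratio, and repeated
randomized trials with confidence intervals.

Every run is fully determined by one master seed; all stage seeds (cohort
generation, partitioning, splitting, initialisation, per-client minibatch
order) are derived from it, so identical specs yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .baseline import BaselineResult, run_baseline
from .cohort import (
    ClientShard,
    CohortConfig,
    feature_cols,
    generate_cohort,
    partition,
    preprocess,
    train_test_split_shard,
)
from .federation import (
    FLConfig,
    FederationResult,
    init_seed,
    predict_with_params,
    run_federation,
)
from .metrics import METRIC_NAMES, IntervalSummary, metrics_report, repeated_ci
from .network import NetworkArchitecture, init_params

logger = logging.getLogger(__name__)

SWEEP_AXES = ("none", "sample_size", "rounds", "split")

# stage tags for seed derivation (distinct from the federation streams 0/1)
_STAGE_COHORT = 10
_STAGE_PARTITION = 11
_STAGE_SPLIT = 12
_STAGE_TRIAL = 1000


def stage_seed(master_seed: int, *key: int) -> int:
    """A reproducible 31-bit integer seed for one pipeline stage."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentSpec:
    """A full experiment: cohort recipe, federation settings, optional sweep."""

    cohort: CohortConfig
    fl: FLConfig
    samples_per_client: int | None = None
    missing_threshold: float = 0.10
    axis: str = "none"
    axis_values: tuple = ()
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"unknown sweep axis {self.axis!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ComparisonReport:
    """Per-client and macro metrics for both arms, plus absolute improvements
    (federated minus isolated baseline, in percentage points)."""

    table: pd.DataFrame  # columns: arm, client, metric, value
    improvements: dict[str, float]  # macro FL − CML, percentage points
    federation: FederationResult
    baseline: BaselineResult
    shards: list[ClientShard]

    def macro(self, arm: str) -> dict[str, float]:
        sub = self.table[(self.table["arm"] == arm) & (self.table["client"] == "macro")]
        return dict(zip(sub["metric"], sub["value"]))


def build_shards(
    cohort_cfg: CohortConfig,
    fl_cfg: FLConfig,
    seed: int,
    samples_per_client: int | None = None,
    missing_threshold: float = 0.10,
) -> list[ClientShard]:
    """Generate → preprocess → partition → split; the shared data pipeline.

    If ``K · samples_per_client`` exceeds the configured cohort, the cohort is
    scaled up proportionally (preserving group and sex ratios) so oversized
    sweep points remain runnable.
    """
    k = fl_cfg.n_clients
    cfg = replace(cohort_cfg, seed=stage_seed(seed, _STAGE_COHORT))
    cohort = preprocess(generate_cohort(cfg), missing_threshold)
    spc = samples_per_client or len(cohort) // k
    if k * spc > len(cohort):
        factor = k * spc / len(cohort) * 1.05
        cfg = replace(cfg.scaled(factor), seed=cfg.seed)
        cohort = preprocess(generate_cohort(cfg), missing_threshold)
        logger.info("cohort scaled to %d records for k=%d x %d", len(cohort), k, spc)
    shards = partition(cohort, k, spc, seed=stage_seed(seed, _STAGE_PARTITION))
    return [
        train_test_split_shard(
            shard, fl_cfg.split, seed=stage_seed(seed, _STAGE_SPLIT, i), client_id=i
        )
        for i, shard in enumerate(shards)
    ]


def _evaluate_arm(arm: str, predictions: pd.DataFrame) -> list[dict]:
    rows = []
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for client, grp in predictions.groupby("client"):
        rep = metrics_report(grp["label"].to_numpy(), grp["prob"].to_numpy())
        for m in METRIC_NAMES:
            rows.append({"arm": arm, "client": str(client), "metric": m, "value": rep[m]})
            per_metric[m].append(rep[m])
    for m in METRIC_NAMES:
        rows.append(
            {"arm": arm, "client": "macro", "metric": m, "value": float(np.mean(per_metric[m]))}
        )
    return rows


def run_comparison(spec: ExperimentSpec, seed: int) -> ComparisonReport:
    """One full federated-vs-isolated comparison on identical shards and init.

    Both arms share the cohort, partition, splits, initial parameters, and
    per-(client, round) minibatch seeds; they differ only in whether the
    server averages parameters between rounds.
    """
    fl_cfg = replace(spec.fl, seed=seed)
    shards = build_shards(
        spec.cohort, fl_cfg, seed, spec.samples_per_client, spec.missing_threshold
    )
    width = len(feature_cols(shards[0].train))
    arch = NetworkArchitecture(
        input_width=width, hidden=fl_cfg.hidden, activation=fl_cfg.activation
    )
    theta0 = init_params(arch, init_seed(seed).integers(2**31))

    fed = run_federation(shards, fl_cfg, initial_params=theta0)
    base = run_baseline(shards, fl_cfg, initial_params=theta0)

    fed_preds = fed.final_round_predictions()
    if fed_preds.empty:  # r=0: score the (untrained) global model directly
        fed_preds = predict_with_params(shards, fed.final_params, fl_cfg.activation)
    rows = _evaluate_arm("COPD_AVG_FL", fed_preds)
    rows += _evaluate_arm("CML", base.final_round_predictions())
    table = pd.DataFrame(rows, columns=["arm", "client", "metric", "value"])

    report = ComparisonReport(
        table=table,
        improvements={},
        federation=fed,
        baseline=base,
        shards=shards,
    )
    fl_macro, cml_macro = report.macro("COPD_AVG_FL"), report.macro("CML")
    report.improvements = {
        m: 100.0 * (fl_macro[m] - cml_macro[m]) for m in METRIC_NAMES
    }
    return report


def run_sweep(spec: ExperimentSpec, seed: int) -> tuple[list[ComparisonReport], pd.DataFrame]:
    """One comparison per axis value, all other settings held at defaults.

    Axis conventions: ``sample_size`` values are per-client record counts;
    ``rounds`` values replace the communication-round count; ``split`` values
    are (train, test) share pairs.  Returns the reports plus a long-format
    frame ``axis_value, arm, client, metric, value``.
    """
    if spec.axis == "none" or not spec.axis_values:
        raise ValueError("sweep requires a nonempty axis")
    reports, rows = [], []
    for value in spec.axis_values:
        if spec.axis == "sample_size":
            point = replace(spec, samples_per_client=int(value), axis="none")
            tag = value
        elif spec.axis == "rounds":
            point = replace(spec, fl=replace(spec.fl, rounds=int(value)), axis="none")
            tag = value
        else:  # split
            tr, te = value
            point = replace(spec, fl=replace(spec.fl, split=(float(tr), float(te))), axis="none")
            tag = f"{tr}:{te}"
        report = run_comparison(point, seed)
        reports.append(report)
        sub = report.table.copy()
        sub.insert(0, "axis_value", tag)
        rows.append(sub)
    return reports, pd.concat(rows, ignore_index=True)


def run_randomized_trials(
    spec: ExperimentSpec, m: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """m independent end-to-end comparisons differing only in derived seeds.

    Returns (summary, raw): normal-theory 95% CIs of each macro metric per
    arm, and the raw per-trial macro values.
    """
    if m < 2:
        raise ValueError("need at least two randomized trials")
    raw_rows = []
    for i in range(m):
        trial_seed = stage_seed(seed, _STAGE_TRIAL, i)
        report = run_comparison(replace(spec, axis="none"), trial_seed)
        for arm in ("CML", "COPD_AVG_FL"):
            macro = report.macro(arm)
            for metric, value in macro.items():
                raw_rows.append(
                    {"trial": i, "arm": arm, "metric": metric, "value": value}
                )
    raw = pd.DataFrame(raw_rows)
    summary_rows = []
    for (arm, metric), grp in raw.groupby(["arm", "metric"], sort=False):
        ci: IntervalSummary = repeated_ci(grp["value"].to_numpy(), metric=metric)
        summary_rows.append(
            {
                "arm": arm,
                "metric": metric,
                "m": ci.m,
                "mean": ci.mean,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
            }
        )
    return pd.DataFrame(summary_rows), raw


def bootstrap_mean_ci(
    values: np.ndarray, n_boot: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of a small sample of run outcomes."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    means = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def make_manifest(spec_doc: dict, seed: int) -> dict:
    """Audit manifest: config hash, seed, and package version for one run."""
    blob = json.dumps(spec_doc, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "fedcopd_version": __version__,
    }
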