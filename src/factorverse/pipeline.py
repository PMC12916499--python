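"""Configuration, dataset I/O and end-to-end orchestration.

A :class:`RunConfig` (YAML-serialisable) describes a reproducible run:
simulation scale, which manipulation arms to execute, per-outcome ranking
directions, and every seed.  ``run_pipeline`` ties the modules together —
simulate -> discovery correlations -> arms -> cross-dataset evaluation ->
PLS comparison -> report files — and stamps every artifact with the config
hash so reruns are verifiable.

Datasets round-trip as plain CSV: a wide response table whose header encodes
the questionnaire mapping (``<questionnaire>__<item>``), one
covariates-plus-outcomes table, an optional ground-truth table, and a JSON
sidecar with the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import multiverse as mv
from . import pls as pls_mod
from .effects import fit_effect, weighted_average
from .exceptions import InvalidArgumentError, ParseError, SchemaError
from .polychoric import heterogeneous_matrix
from .simulate import (
    CONFIDENCE,
    PLANNING,
    SyntheticDataset,
    attach_cognition,
    build_default_spec,
    default_cognition_specs,
    simulate_responses,
)

log = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "gender", "iq")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    n_questionnaires: int = 5
    items_per_questionnaire: list = field(default_factory=lambda: [8, 8, 8, 8, 8])
    n_factors: int = 3
    n_datasets: int = 3
    n_per_dataset: int = 500
    discovery_id: str = "discovery"
    arms: list = field(default_factory=lambda: ["combination"])
    k_max: dict = field(default_factory=lambda: {
        "factor_number": 10, "combination": 3, "rotation": 3})
    directions: dict = field(default_factory=lambda: {
        PLANNING: ["most_negative"],
        CONFIDENCE: ["most_positive", "most_negative"]})
    standardization: str = "discovery_z"
    run_pls: bool = True
    seeds: dict = field(default_factory=lambda: {
        "simulation": 1, "rotation": 0, "split": 2, "cv": 3})
    output_dir: str = "artifacts"

    def validate(self) -> None:
        if self.discovery_id != "discovery":
            raise InvalidArgumentError(
                f"discovery id {self.discovery_id!r} not among simulated datasets"
            )
        for arm in self.arms:
            if arm not in mv.ARMS:
                raise InvalidArgumentError(f"unknown arm {arm!r}")
        for outcome, dirs in self.directions.items():
            for d in dirs:
                if d not in mv.DIRECTIONS:
                    raise InvalidArgumentError(f"unknown direction {d!r}")
        required = {"simulation", "rotation", "split", "cv"}
        if not required <= set(self.seeds):
            raise InvalidArgumentError(f"seeds must include {sorted(required)}")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def save_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write a dataset as CSVs plus a JSON seed sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.responses.to_csv(directory / "responses.csv")
    dataset.covariates.join(dataset.outcomes).to_csv(directory / "covariates_outcomes.csv")
    if not dataset.true_factor_scores.empty:
        dataset.true_factor_scores.to_csv(directory / "true_factor_scores.csv")
    meta = {"seed": dataset.seed, "name": dataset.name,
            "n": dataset.n, "outcomes": list(dataset.outcomes.columns)}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset(directory, *, declared_categories: int | None = None) -> SyntheticDataset:
    """Load and validate a dataset written by :func:`save_dataset`.

    Item columns must follow the ``<questionnaire>__<item>`` convention;
    responses must be integers (optionally within ``declared_categories``).
    """
    directory = Path(directory)
    responses = pd.read_csv(directory / "responses.csv", index_col=0)
    for col in responses.columns:
        if "__" not in col:
            raise SchemaError(f"unknown item column {col!r} (expected '<questionnaire>__<item>')")
    float_vals = responses.to_numpy()
    int_vals = float_vals.astype(np.int64, casting="unsafe")
    if not np.array_equal(float_vals, int_vals):
        bad = int(np.argwhere(float_vals != int_vals)[0][0])
        raise ParseError(f"non-integer response at row index {responses.index[bad]}")
    if declared_categories is not None:
        out_of_range = (int_vals < 0) | (int_vals >= declared_categories)
        if out_of_range.any():
            bad = int(np.argwhere(out_of_range.any(axis=1))[0][0])
            raise ParseError(
                f"response outside declared range at row index {responses.index[bad]}"
            )
    responses = pd.DataFrame(int_vals, index=responses.index, columns=responses.columns)

    covout = pd.read_csv(directory / "covariates_outcomes.csv", index_col=0)
    missing = [c for c in COVARIATE_COLUMNS if c not in covout.columns]
    if missing:
        raise SchemaError(f"missing covariate column(s): {missing}")
    covariates = covout[list(COVARIATE_COLUMNS)]
    outcomes = covout.drop(columns=list(COVARIATE_COLUMNS))

    truth_path = directory / "true_factor_scores.csv"
    truth = (pd.read_csv(truth_path, index_col=0) if truth_path.exists()
             else pd.DataFrame(index=responses.index))
    meta = json.loads((directory / "meta.json").read_text())
    qmap = {c: c.split("__")[0] for c in responses.columns}
    return SyntheticDataset(
        responses=responses, covariates=covariates, outcomes=outcomes,
        true_factor_scores=truth, questionnaire_of_item=qmap,
        seed=int(meta.get("seed", -1)), name=meta.get("name", directory.name),
    )


def _simulate_datasets(config: RunConfig) -> list[SyntheticDataset]:
    spec = build_default_spec(
        config.n_questionnaires,
        config.items_per_questionnaire,
        config.n_factors,
        seed=config.seeds["simulation"],
    )
    factors = spec.factors
    cogs = default_cognition_specs()
    base = config.seeds["simulation"]
    datasets = []
    for i in range(config.n_datasets):
        child = (base * 100003 + 7919 * i + 1) % (2 ** 31)
        ds = simulate_responses(spec, config.n_per_dataset, child)
        ds.name = "discovery" if i == 0 else f"replication_{i}"
        for j, cs in enumerate(cogs.values()):
            targets = cs.target_f2_per_factor
            if not set(targets) <= set(factors):
                # generic factor labels: plant the same magnitudes on the
                # first factors in order
                targets = {factors[idx]: v for idx, v in enumerate(targets.values())}
            planted = type(cs)(outcome_label=cs.outcome_label,
                               target_f2_per_factor=targets,
                               covariate_effects=cs.covariate_effects,
                               noise_sd=cs.noise_sd)
            ds = attach_cognition(ds, planted, (child + 31 * (j + 1)) % (2 ** 31),
                                  factor_corr=spec.factor_corr)
        datasets.append(ds)
    return datasets


def _match_benchmark_factors(candidates, discovery) -> dict:
    """Label benchmark factors by their correlation with true factor scores
    (synthetic ground truth); greedy assignment by |r|."""
    truth = discovery.true_factor_scores
    if truth.empty:
        return {}
    pairs = []
    for cand in candidates:
        s = cand.score(discovery.responses).scores
        for label in truth.columns:
            r = float(np.corrcoef(s, truth[label])[0, 1])
            pairs.append((abs(r), label, cand))
    out: dict = {}
    used = set()
    for _, label, cand in sorted(pairs, reverse=True, key=lambda t: t[0]):
        if label in out or cand.candidate_id in used:
            continue
        out[label] = cand
        used.add(cand.candidate_id)
    return out


def run_pipeline(config: RunConfig, output_dir=None) -> Path:
    """Execute a full configured run; returns the artifact directory."""
    config.validate()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seeds": config.seeds}

    stage = "simulate"
    try:
        datasets = _simulate_datasets(config)
        discovery = datasets[0]

        stage = "discovery_correlations"
        R = heterogeneous_matrix(discovery.responses)

        stage = "benchmark"
        bench_candidates = mv.run_factor_number_arm(
            discovery, k_max=min(3, config.n_factors), R=R,
            seed=config.seeds["rotation"])
        bench_by_solution = [c for c in bench_candidates
                             if c.k == min(3, config.n_factors)]
        labels = _match_benchmark_factors(bench_by_solution, discovery)

        stage = "arms"
        arm_candidates: dict = {}
        for arm in config.arms:
            if arm == "factor_number":
                arm_candidates[arm] = mv.run_factor_number_arm(
                    discovery, config.k_max["factor_number"], R=R,
                    seed=config.seeds["rotation"])
            elif arm == "combination":
                arm_candidates[arm] = mv.run_combination_arm(
                    discovery, config.k_max["combination"], R=R,
                    seed=config.seeds["rotation"])
            elif arm == "rotation":
                arm_candidates[arm] = mv.run_rotation_arm(
                    discovery, config.k_max["rotation"], R=R,
                    seed=config.seeds["rotation"])

        stage = "evaluate"
        tables = {}
        summary_winners = {}
        for arm, candidates in arm_candidates.items():
            conditioning = "alone" if arm == "combination" else "joint"
            for outcome, dirs in config.directions.items():
                for direction in dirs:
                    bench_cond = None
                    if arm == "combination" and outcome == CONFIDENCE and labels:
                        # control over/underconfidence models for the
                        # opposing benchmark dimension
                        key = "AD" if direction == "most_positive" else "CIT"
                        bench = labels.get(key) or next(iter(labels.values()))
                        bench_cond = {
                            ds.name: bench.score(ds.responses, config.standardization)
                            for ds in datasets
                        }
                    table = mv.evaluate_candidates(
                        candidates, datasets, outcome, direction,
                        conditioning=conditioning,
                        benchmark_conditioning=bench_cond,
                        standardization=config.standardization,
                    )
                    tables[(arm, outcome, direction)] = table
                    win = table.winner()
                    summary_winners[f"{arm}|{outcome}|{direction}"] = {
                        "candidate_id": win["candidate_id"],
                        "f2_weighted": float(win["f2_weighted"]),
                        "percentile_beaten": float(win["percentile_beaten"]),
                    }

        stage = "pls"
        pls_summary = {}
        if config.run_pls and labels:
            pls_summary = _pls_comparison(config, datasets, labels)

        stage = "report"
        write_report(tables, arm_candidates, out,
                     summary={"winners": summary_winners, "pls": pls_summary,
                              **stamp})
    except Exception:
        log.exception("pipeline failed at stage %r; partial artifacts in %s",
                      stage, out)
        (out / "FAILED_STAGE.txt").write_text(stage)
        raise
    return out


def _pls_comparison(config: RunConfig, datasets, labels) -> dict:
    """Head-to-head: PLS planning component vs the benchmark compulsivity
    factor, out of sample."""
    discovery = datasets[0]
    bench = labels.get("CIT") or next(iter(labels.values()))
    resid = pls_mod.residualize(discovery.outcomes[PLANNING], discovery.covariates)
    train_idx, _ = pls_mod.split_train_test(discovery, 0.75,
                                            seed=config.seeds["split"])
    X_train = discovery.responses.loc[train_idx]
    y_train = resid.loc[train_idx]
    model = pls_mod.select_components_cv(
        X_train, y_train, k_folds=10,
        max_components=min(5, len(train_idx) // 20 or 1),
        seed=config.seeds["cv"])
    model.split_seed = config.seeds["split"]

    pls_scores_disc = pls_mod.pls_component_scores(discovery.responses, model)
    bench_scores_disc = bench.score(discovery.responses, config.standardization)
    r = float(np.corrcoef(pls_scores_disc.scores, bench_scores_disc.scores)[0, 1])

    holdout = [ds for ds in datasets if ds.name != discovery.name]
    recs_pls, recs_bench = [], []
    for ds in holdout:
        recs_pls.append(fit_effect(ds.outcomes[PLANNING],
                                   pls_mod.pls_component_scores(ds.responses, model),
                                   ds.covariates, dataset_id=ds.name))
        recs_bench.append(fit_effect(ds.outcomes[PLANNING],
                                     bench.score(ds.responses, config.standardization),
                                     ds.covariates, dataset_id=ds.name))
    f2_pls = weighted_average(recs_pls).f2_weighted if recs_pls else float("nan")
    f2_bench = weighted_average(recs_bench).f2_weighted if recs_bench else float("nan")
    return {
        "n_components": model.n_components,
        "cv_rmse_per_c": model.cv_rmse_per_c,
        "discovery_score_correlation": r,
        "f2_weighted_pls": f2_pls,
        "f2_weighted_benchmark": f2_bench,
        "f2_gain": (abs(f2_pls) - abs(f2_bench)
                    if np.isfinite(f2_pls) and np.isfinite(f2_bench) else float("nan")),
    }


def write_report(tables: dict, arm_candidates: dict, output_dir,
                 summary: dict | None = None) -> list[Path]:
    """Write evaluation tables, the candidate registry and a JSON summary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = []
    for (arm, outcome, direction), table in sorted(tables.items()):
        t = table.table.copy()
        t.insert(1, "outcome", outcome)
        t.insert(2, "direction", direction)
        frames.append(t)
    if frames:
        big = pd.concat(frames, ignore_index=True)
    else:
        big = pd.DataFrame({"empty": ["no evaluations were run"]})
    path = out / "multiverse_table.csv"
    big.to_csv(path, index=False)
    written.append(path)

    cand_rows = []
    for arm, candidates in sorted(arm_candidates.items()):
        for c in candidates:
            cand_rows.append({
                "candidate_id": c.candidate_id, "arm": c.arm,
                "questionnaire_subset": "+".join(c.questionnaire_subset),
                "k": c.k, "factor_index": c.factor_index,
                "converged": c.converged,
            })
    cand_path = out / "candidates.csv"
    pd.DataFrame(cand_rows).to_csv(cand_path, index=False)
    written.append(cand_path)

    summary = dict(summary or {})
    if not tables:
        summary["empty_result"] = True
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    written.append(summary_path)
    return written
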