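"""Enumeration and evaluation of the candidate-dimension multiverse.

Three manipulation arms generate candidate latent dimensions from a single
discovery dataset:

* ``factor_number`` — one-to-k_max-factor oblimin solutions on the full item
  set (k_max = 10 gives 55 candidates);
* ``combination`` — every non-empty questionnaire subset crossed with
  one-to-k_max-factor solutions (nine questionnaires at k_max = 5 enumerate
  7665 candidates);
* ``rotation`` — oblimin, varimax and a Schmid-Leiman bifactor solution at a
  fixed k (k = 3 gives 10 candidates, the bifactor contributing a general
  factor).

Each candidate carries item weights (regression score weights, or
Anderson-Rubin weights for bifactor candidates) that can be applied to any
dataset; candidates are then ranked by sample-size-weighted signed Cohen's
f-squared against a cognitive outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .effects import DimensionScores, apply_weights, fit_effect, weighted_average
from .efa import (
    anderson_rubin_scores,
    bifactor_schmid_leiman,
    extract_ml,
    identification_df,
    regression_score_weights,
    rotate,
)
from .exceptions import InvalidArgumentError
from .polychoric import HetCorMatrix, ensure_psd, heterogeneous_matrix

log = logging.getLogger(__name__)

ARMS = ("factor_number", "combination", "rotation")
DIRECTIONS = ("most_negative", "most_positive")


@dataclass
class CandidateDimension:
    """One factor from one multiverse cell, with portable item weights."""

    candidate_id: str
    arm: str
    questionnaire_subset: tuple
    k: int
    factor_index: object               # 1..k, or "general"
    item_weights: pd.Series
    item_loadings: pd.Series
    converged: bool
    scale_means: pd.Series             # discovery item means (for discovery_z)
    scale_sds: pd.Series
    solution_key: str                  # shared by factors of one fitted model

    def score(self, responses: pd.DataFrame,
              standardization: str = "discovery_z") -> DimensionScores:
        return apply_weights(
            responses, self.item_weights, standardization,
            item_means=self.scale_means, item_sds=self.scale_sds,
            dimension_id=self.candidate_id,
        )


@dataclass
class MultiverseTable:
    """Candidates x datasets effect grid with ranks and percentiles."""

    table: pd.DataFrame
    outcome_label: str
    direction: str
    excluded: list = field(default_factory=list)

    def winner(self) -> pd.Series:
        ranked = self.table.dropna(subset=["rank"])
        return ranked.sort_values(["rank", "candidate_id"]).iloc[0]


def enumerate_subsets(questionnaires: list) -> list[tuple]:
    """All non-empty subsets, ordered by size then lexicographically."""
    labels = list(questionnaires)
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate questionnaire labels")
    if not labels:
        raise InvalidArgumentError("need at least one questionnaire")
    out = []
    for size in range(1, len(labels) + 1):
        out.extend(sorted(combinations(sorted(labels), size)))
    return out


def combination_grid(questionnaires: list, k_max: int) -> list[tuple]:
    """All (subset, k) fitting cells of the combination arm; the number of
    enumerated candidate dimensions is ``sum(k for _, k in grid)``."""
    if k_max < 1:
        raise InvalidArgumentError("k_max must be >= 1")
    return [(subset, k) for subset in enumerate_subsets(questionnaires)
            for k in range(1, k_max + 1)]


def count_candidates(n_questionnaires: int, k_max: int) -> int:
    """Enumerated combination-arm candidates for q questionnaires."""
    return (2 ** n_questionnaires - 1) * k_max * (k_max + 1) // 2


def discovery_correlations(discovery, **kwargs) -> HetCorMatrix:
    """Heterogeneous correlation matrix of the discovery responses."""
    return heterogeneous_matrix(discovery.responses, **kwargs)


def _discovery_stats(discovery):
    resp = discovery.responses
    means = resp.mean(axis=0)
    sds = resp.std(axis=0, ddof=0)
    return means, sds


def _fit_cell(R_sub: HetCorMatrix, k: int, n: int, arm: str,
              subset: tuple, means, sds, *, seed: int = 0,
              id_prefix: str | None = None) -> list[CandidateDimension]:
    """Fit one (subset, k) cell with ML + oblimin; one candidate per factor."""
    sol = rotate(extract_ml(ensure_psd(R_sub.matrix), k, n, seed=seed),
                 "oblimin", seed=seed)
    weights = regression_score_weights(ensure_psd(R_sub.matrix).matrix, sol)
    prefix = id_prefix or f"{arm}|{'+'.join(subset)}|k{k}"
    items = sol.items
    out = []
    for j, col in enumerate(sol.loadings.columns):
        out.append(CandidateDimension(
            candidate_id=f"{prefix}|f{j + 1}",
            arm=arm,
            questionnaire_subset=subset,
            k=k,
            factor_index=j + 1,
            item_weights=weights[col],
            item_loadings=sol.loadings[col],
            converged=sol.converged,
            scale_means=means.loc[items],
            scale_sds=sds.loc[items],
            solution_key=prefix,
        ))
    return out


def run_factor_number_arm(discovery, k_max: int = 10, *,
                          R: HetCorMatrix | None = None,
                          seed: int = 0) -> list[CandidateDimension]:
    """Arm (i): vary the number of retained factors on the full item set."""
    if k_max < 1:
        raise InvalidArgumentError("k_max must be >= 1")
    R = R if R is not None else discovery_correlations(discovery)
    means, sds = _discovery_stats(discovery)
    all_q = tuple(sorted(discovery.questionnaires()))
    n = len(discovery.responses)
    candidates = []
    for k in range(1, k_max + 1):
        candidates.extend(_fit_cell(R, k, n, "factor_number", all_q, means, sds,
                                    seed=seed, id_prefix=f"factor_number|k{k}"))
    return candidates


def run_combination_arm(discovery, k_max: int = 5, *,
                        R: HetCorMatrix | None = None,
                        questionnaires: list | None = None,
                        seed: int = 0) -> list[CandidateDimension]:
    """Arm (ii): vary the questionnaire subset, crossed with 1..k_max factors.

    Pairwise polychoric estimates do not depend on which other items are in
    the analysis, so the full-matrix estimates are sliced per subset (with a
    fresh PSD repair).  Cells violating the ML identification bound are
    skipped and logged; fit failures yield ``converged=False`` candidates.
    """
    qmap = discovery.questionnaires()
    labels = sorted(questionnaires) if questionnaires is not None else sorted(qmap)
    unknown = set(labels) - set(qmap)
    if unknown:
        raise InvalidArgumentError(f"unknown questionnaires: {sorted(unknown)}")
    items_all = [i for q in labels for i in qmap[q]]
    sub_resp = discovery.responses[items_all]
    R = R if R is not None else heterogeneous_matrix(sub_resp)
    means, sds = _discovery_stats(discovery)
    n = len(discovery.responses)

    candidates, skipped = [], []
    for subset, k in combination_grid(labels, k_max):
        items = [i for q in subset for i in qmap[q]]
        if identification_df(len(items), k) < 0:
            skipped.append((subset, k))
            continue
        R_sub = R.submatrix(items)
        candidates.extend(_fit_cell(R_sub, k, n, "combination", subset,
                                    means, sds, seed=seed))
    if skipped:
        log.info("combination arm: skipped %d under-identified cells: %s",
                 len(skipped), skipped)
    return candidates


def run_rotation_arm(discovery, k: int = 3, *,
                     R: HetCorMatrix | None = None,
                     seed: int = 0) -> list[CandidateDimension]:
    """Arm (iii): oblimin vs varimax vs Schmid-Leiman bifactor at fixed k.

    Produces 3k + 1 candidates.  Bifactor candidates (general + k group
    factors) carry Anderson-Rubin weights computed on the discovery sample so
    their discovery scores are exactly mutually orthogonal.
    """
    R = R if R is not None else discovery_correlations(discovery)
    R_psd = ensure_psd(R.matrix)
    means, sds = _discovery_stats(discovery)
    all_q = tuple(sorted(discovery.questionnaires()))
    n = len(discovery.responses)
    unrotated = extract_ml(R_psd, k, n, seed=seed)
    candidates = []
    for method in ("oblimin", "varimax"):
        sol = rotate(unrotated, method, seed=seed)
        weights = regression_score_weights(R_psd.matrix, sol)
        prefix = f"rotation|{method}|k{k}"
        for j, col in enumerate(sol.loadings.columns):
            candidates.append(CandidateDimension(
                candidate_id=f"{prefix}|f{j + 1}",
                arm="rotation", questionnaire_subset=all_q, k=k,
                factor_index=j + 1,
                item_weights=weights[col], item_loadings=sol.loadings[col],
                converged=sol.converged,
                scale_means=means, scale_sds=sds,
                solution_key=prefix,
            ))

    bif = bifactor_schmid_leiman(R_psd, k, n, rotation_seed=seed)
    Z = (discovery.responses - means) / sds
    _, ar_weights = anderson_rubin_scores(Z, R_psd.matrix, bif.scoring_loadings)
    prefix = f"rotation|bifactor|k{k}"
    loadings = bif.combined_loadings()
    for col in ar_weights.columns:
        candidates.append(CandidateDimension(
            candidate_id=f"{prefix}|{col}",
            arm="rotation", questionnaire_subset=all_q, k=k,
            factor_index="general" if col == "general" else int(col.lstrip("G")),
            item_weights=ar_weights[col], item_loadings=loadings[col],
            converged=bif.source.converged,
            scale_means=means, scale_sds=sds,
            solution_key=prefix,
        ))
    return candidates


def _rank_key(f2: float, direction: str) -> float:
    return f2 if direction == "most_negative" else -f2


def evaluate_candidates(
    candidates: list[CandidateDimension],
    datasets: list,
    outcome_label: str,
    direction: str,
    *,
    conditioning: str = "joint",
    benchmark_conditioning: dict | None = None,
    standardization: str = "discovery_z",
    percentile_convention: str = "strict",
) -> MultiverseTable:
    """Score, regress and rank every candidate across datasets.

    ``conditioning='joint'`` enters all factors of the same fitted solution
    into one regression (factor-number and rotation arms);
    ``conditioning='alone'`` enters the focal factor only (combination arm),
    optionally with per-dataset benchmark scores added as covariates via
    ``benchmark_conditioning`` ({dataset_name: DimensionScores}).  Candidates
    without a converged fit are retained as rows but excluded from ranking.
    Ranking is by weighted f2 in the stated direction with ties sharing the
    smallest rank; ``percentile_beaten`` is the share of strictly worse
    ranked candidates (the ``'rank'`` convention uses (m - rank) / m).
    """
    if direction not in DIRECTIONS:
        raise InvalidArgumentError(f"unknown direction {direction!r}")
    if conditioning not in ("joint", "alone"):
        raise InvalidArgumentError(f"unknown conditioning {conditioning!r}")
    if not candidates:
        raise InvalidArgumentError("no candidates to evaluate")

    by_solution: dict = {}
    for cand in candidates:
        by_solution.setdefault(cand.solution_key, []).append(cand)

    rows = []
    excluded = [c.candidate_id for c in candidates if not c.converged]
    dataset_names = sorted(ds.name for ds in datasets)
    per_dataset_scores = []
    for ds in sorted(datasets, key=lambda d: d.name):
        scores = {c.candidate_id: c.score(ds.responses, standardization)
                  for c in candidates}
        per_dataset_scores.append((ds, scores))

    for cand in candidates:
        effects = []
        per_ds = {}
        for ds, scores in per_dataset_scores:
            focal = scores[cand.candidate_id]
            if conditioning == "joint":
                cond = [scores[sib.candidate_id]
                        for sib in by_solution[cand.solution_key]
                        if sib.candidate_id != cand.candidate_id]
            else:
                cond = []
            if benchmark_conditioning and ds.name in benchmark_conditioning:
                bench = benchmark_conditioning[ds.name]
                # the benchmark dimension is itself part of the multiverse:
                # when the focal candidate (near-)duplicates it, the aliased
                # covariate is dropped, as a fixed-effects solver would do
                r = float(np.corrcoef(focal.scores, bench.scores)[0, 1])
                if bench.dimension_id != cand.candidate_id and abs(r) < 0.999:
                    cond = cond + [bench]
            rec = fit_effect(ds.outcomes[outcome_label], focal,
                             ds.covariates, cond, dataset_id=ds.name)
            per_ds[ds.name] = rec
            effects.append(rec)
        pooled = weighted_average(effects)
        row = {
            "candidate_id": cand.candidate_id,
            "arm": cand.arm,
            "questionnaire_subset": "+".join(cand.questionnaire_subset),
            "k": cand.k,
            "factor_index": cand.factor_index,
            "converged": cand.converged,
            "f2_weighted": pooled.f2_weighted,
        }
        for name in dataset_names:
            row[f"f2_{name}"] = per_ds[name].f2_signed
            row[f"p_{name}"] = per_ds[name].p_value
        rows.append(row)

    table = pd.DataFrame(rows).sort_values("candidate_id").reset_index(drop=True)
    ranked_mask = table["converged"].to_numpy()
    keys = np.array([_rank_key(f, direction) for f in table["f2_weighted"]])
    tie = -np.abs(table["f2_weighted"].to_numpy())

    ranks = np.full(len(table), np.nan)
    pct = np.full(len(table), np.nan)
    idx = np.where(ranked_mask)[0]
    m = len(idx)
    if m:
        kk = keys[idx]
        tt = tie[idx]
        order = np.lexsort((list(table["candidate_id"][idx]), tt, kk))
        # min-rank with ties on (key, tie)
        rank_vals = np.empty(m)
        sorted_pairs = [(kk[o], tt[o]) for o in order]
        r = 1
        for pos, o in enumerate(order):
            if pos > 0 and sorted_pairs[pos] != sorted_pairs[pos - 1]:
                r = pos + 1
            rank_vals[o] = r
        for pos, o in enumerate(order):
            worse = sum(1 for q in range(m)
                        if (kk[q], tt[q]) > (kk[o], tt[o]))
            if percentile_convention == "strict":
                pct[idx[o]] = 100.0 * worse / (m - 1) if m > 1 else 100.0
            elif percentile_convention == "rank":
                pct[idx[o]] = 100.0 * (m - rank_vals[o]) / m
            else:
                raise InvalidArgumentError(
                    f"unknown percentile convention {percentile_convention!r}"
                )
        ranks[idx] = rank_vals
    table["rank"] = ranks
    table["percentile_beaten"] = pct
    return MultiverseTable(table=table, outcome_label=outcome_label,
                           direction=direction, excluded=excluded)


@dataclass
class BenchmarkComparison:
    score_correlation: float
    loading_correlation: float
    flipped: bool


def compare_to_benchmark(candidate: CandidateDimension,
                         benchmark: CandidateDimension,
                         discovery,
                         *, sign_align: bool = True,
                         standardization: str = "discovery_z") -> BenchmarkComparison:
    """Pearson correlations of discovery scores and of shared-item loadings.

    With ``sign_align`` (default), both correlations are negated when the
    score correlation is negative — factor sign is arbitrary — and the flip
    is recorded.
    """
    s_c = candidate.score(discovery.responses, standardization).scores
    s_b = benchmark.score(discovery.responses, standardization).scores
    shared = candidate.item_loadings.index.intersection(benchmark.item_loadings.index)
    if len(shared) == 0:
        raise InvalidArgumentError("no shared items between candidate and benchmark")
    r_scores = float(np.corrcoef(s_c, s_b)[0, 1])
    r_load = float(np.corrcoef(candidate.item_loadings[shared],
                               benchmark.item_loadings[shared])[0, 1])
    flipped = False
    if sign_align and r_scores < 0:
        r_scores, r_load, flipped = -r_scores, -r_load, True
    return BenchmarkComparison(score_correlation=r_scores,
                               loading_correlation=r_load, flipped=flipped)
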