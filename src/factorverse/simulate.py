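"""Synthetic ordinal questionnaire data with planted latent structure.

The generator emulates the statistical shape of large online transdiagnostic
studies: a battery of nine clinical questionnaires (209 Likert-type items)
whose inter-item correlations arise from an oblique three-factor model
(anxious-depression, compulsivity and intrusive thought, social withdrawal),
demographic covariates, and scalar cognitive outcomes (model-based planning,
mean confidence) whose *partial* effect sizes against the latent factors are
planted as signed Cohen's f-squared values.

Item latent variates are standardised to unit variance so that, under
orthogonal factors, loadings equal item-factor correlations and the implied
polychoric correlation between two items is analytically available as
``lam_i Phi lam_j'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import InvalidArgumentError

# Default questionnaire battery: the nine instruments and item counts of the
# standard 209-item transdiagnostic set, each keyed to the latent factor that
# dominates it.
DEFAULT_QUESTIONNAIRES = (
    ("SDS", 20, "AD"),    # self-rating depression
    ("STAI", 20, "AD"),   # trait anxiety
    ("AES", 18, "AD"),    # apathy
    ("OCI", 18, "CIT"),   # obsessive-compulsive
    ("SCZ", 43, "CIT"),   # schizotypy
    ("EAT", 26, "CIT"),   # eating attitudes
    ("BIS", 30, "CIT"),   # impulsiveness
    ("AUDIT", 10, "CIT"),  # alcohol use
    ("LSAS", 24, "SW"),   # social anxiety
)
DEFAULT_FACTORS = ("AD", "CIT", "SW")
# Oblique factor correlations: anxious-depression correlates most strongly
# with social withdrawal, moderately with compulsivity.
DEFAULT_FACTOR_CORR = np.array([
    [1.0, 0.4, 0.5],
    [0.4, 1.0, 0.3],
    [0.5, 0.3, 1.0],
])

PLANNING = "model_based_planning"
CONFIDENCE = "mean_confidence"


@dataclass
class LatentSpec:
    """Planted measurement model for ordinal items.

    ``loading_matrix`` holds pattern coefficients (items x factors) and
    ``factor_corr`` the oblique factor correlations; together they imply each
    item's communality, which must not exceed 1.  ``item_thresholds`` are the
    ordered latent cut-points defining the ordinal categories.
    """

    loading_matrix: pd.DataFrame
    factor_corr: np.ndarray
    item_thresholds: dict
    questionnaire_of_item: dict
    n_categories: dict

    def __post_init__(self):
        Phi = np.asarray(self.factor_corr, dtype=float)
        if not np.allclose(Phi, Phi.T, atol=1e-10):
            raise InvalidArgumentError("factor_corr must be symmetric")
        if not np.allclose(np.diag(Phi), 1.0):
            raise InvalidArgumentError("factor_corr must have a unit diagonal")
        if np.linalg.eigvalsh(Phi)[0] <= 0:
            raise InvalidArgumentError("factor_corr must be positive definite")
        self.factor_corr = Phi
        L = self.loading_matrix.to_numpy()
        comm = np.einsum("ij,jk,ik->i", L, Phi, L)
        if (comm > 1.0 + 1e-10).any():
            bad = self.loading_matrix.index[comm > 1.0 + 1e-10][0]
            raise InvalidArgumentError(f"implied communality exceeds 1 for item {bad!r}")
        for item, t in self.item_thresholds.items():
            t = np.asarray(t, dtype=float)
            if (np.diff(t) <= 0).any():
                raise InvalidArgumentError(f"thresholds not strictly increasing for {item!r}")
            if len(t) != self.n_categories[item] - 1:
                raise InvalidArgumentError(f"threshold count mismatch for {item!r}")
        missing = set(self.loading_matrix.index) - set(self.questionnaire_of_item)
        if missing:
            raise InvalidArgumentError(f"items without questionnaire: {sorted(missing)[:5]}")

    @property
    def items(self):
        return list(self.loading_matrix.index)

    @property
    def factors(self):
        return list(self.loading_matrix.columns)

    @property
    def n_factors(self) -> int:
        return self.loading_matrix.shape[1]

    def questionnaires(self) -> dict:
        out: dict = {}
        for item in self.items:
            out.setdefault(self.questionnaire_of_item[item], []).append(item)
        return out

    def communalities(self) -> pd.Series:
        L = self.loading_matrix.to_numpy()
        return pd.Series(np.einsum("ij,jk,ik->i", L, self.factor_corr, L),
                         index=self.loading_matrix.index)

    def implied_item_correlation(self, item_a: str, item_b: str) -> float:
        """Population polychoric correlation between two items' latents."""
        la = self.loading_matrix.loc[item_a].to_numpy()
        lb = self.loading_matrix.loc[item_b].to_numpy()
        return float(la @ self.factor_corr @ lb)


@dataclass
class CognitionSpec:
    """Planted outcome model: signed partial effect sizes per latent factor.

    ``target_f2_per_factor`` maps factor label to the population signed
    Cohen's f-squared of that factor, conditioning on the remaining factors
    and the covariates.  ``covariate_effects`` are standardised coefficients.
    """

    outcome_label: str
    target_f2_per_factor: dict
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be positive")
        for factor, f2 in self.target_f2_per_factor.items():
            if abs(f2) >= 1.0:
                raise InvalidArgumentError(
                    f"|target f2| must be < 1 (factor {factor!r}: {f2})"
                )


@dataclass
class SyntheticDataset:
    """One simulated study: responses, covariates, outcomes, ground truth."""

    responses: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    true_factor_scores: pd.DataFrame
    questionnaire_of_item: dict
    seed: int
    name: str = "synthetic"

    def __post_init__(self):
        n = len(self.responses)
        for block in (self.covariates, self.outcomes, self.true_factor_scores):
            if len(block) != n or not block.index.equals(self.responses.index):
                raise InvalidArgumentError("participant blocks misaligned")

    @property
    def n(self) -> int:
        return len(self.responses)

    def questionnaires(self) -> dict:
        out: dict = {}
        for item in self.responses.columns:
            out.setdefault(self.questionnaire_of_item[item], []).append(item)
        return out


def build_default_spec(
    n_questionnaires: int = 9,
    items_per_questionnaire=None,
    n_factors: int = 3,
    *,
    n_categories: int = 4,
    seed: int = 0,
) -> LatentSpec:
    """Construct a simple-structure latent spec.

    Defaults reproduce the 209-item / nine-questionnaire battery with three
    oblique factors.  With non-default sizes, questionnaires are labelled
    ``Q1..Qn``, assigned round-robin to generic factors ``F1..Fk``.  Dominant
    loadings are drawn uniformly in (0.45, 0.75), cross-loadings in
    (0, 0.15); thresholds are right-skewed (symptom endorsement is rare) with
    per-item jitter.  Fully deterministic given ``seed``.
    """
    if n_questionnaires < 1 or n_factors < 1:
        raise InvalidArgumentError("counts must be positive")
    default_battery = (
        n_questionnaires == 9 and items_per_questionnaire is None and n_factors == 3
    )
    if default_battery:
        battery = list(DEFAULT_QUESTIONNAIRES)
        factors = list(DEFAULT_FACTORS)
        Phi = DEFAULT_FACTOR_CORR.copy()
    else:
        if items_per_questionnaire is None:
            items_per_questionnaire = [8] * n_questionnaires
        items_per_questionnaire = list(items_per_questionnaire)
        if len(items_per_questionnaire) != n_questionnaires:
            raise InvalidArgumentError("items_per_questionnaire length mismatch")
        if any(c <= 0 for c in items_per_questionnaire):
            raise InvalidArgumentError("every questionnaire needs at least one item")
        factors = [f"F{j + 1}" for j in range(n_factors)]
        battery = [
            (f"Q{i + 1}", items_per_questionnaire[i], factors[i % n_factors])
            for i in range(n_questionnaires)
        ]
        Phi = np.full((n_factors, n_factors), 0.3)
        np.fill_diagonal(Phi, 1.0)
    if n_factors > sum(c for _, c, _ in battery):
        raise InvalidArgumentError("more factors than items")

    rng = np.random.default_rng(seed)
    rows, loadings = [], []
    questionnaire_of_item: dict = {}
    for label, count, dominant in battery:
        j = factors.index(dominant)
        for i in range(count):
            item = f"{label}__{i + 1:02d}"
            lam = rng.uniform(0.0, 0.15, size=n_factors)
            lam[j] = rng.uniform(0.45, 0.75)
            rows.append(item)
            loadings.append(lam)
            questionnaire_of_item[item] = label

    loading_matrix = pd.DataFrame(loadings, index=rows, columns=factors)
    # Right-skewed Likert distribution: most mass in the lowest categories.
    base = np.linspace(0.35, 0.92, n_categories - 1)
    item_thresholds, cats = {}, {}
    for item in rows:
        probs = np.clip(base + rng.uniform(-0.05, 0.05, size=n_categories - 1), 0.02, 0.98)
        probs = np.sort(probs)
        item_thresholds[item] = ndtri(probs)
        cats[item] = n_categories
    return LatentSpec(
        loading_matrix=loading_matrix,
        factor_corr=Phi,
        item_thresholds=item_thresholds,
        questionnaire_of_item=questionnaire_of_item,
        n_categories=cats,
    )


def simulate_responses(spec: LatentSpec, n: int, seed: int) -> SyntheticDataset:
    """Draw ordinal responses and demographic covariates from a latent spec.

    Factor scores are multivariate normal with covariance ``factor_corr``;
    each item's latent value is its loading row times the factor scores plus
    unique normal noise scaled so the latent variance is 1; the ordinal
    response is the count of thresholds below the latent value (0-based).
    """
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    rng = np.random.default_rng(seed)
    Phi = spec.factor_corr
    try:
        chol = np.linalg.cholesky(Phi)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError("factor_corr is not positive definite") from exc

    F = rng.standard_normal((n, spec.n_factors)) @ chol.T
    L = spec.loading_matrix.to_numpy()
    comm = np.einsum("ij,jk,ik->i", L, Phi, L)
    unique_sd = np.sqrt(np.clip(1.0 - comm, 0.0, None))
    latent = F @ L.T + rng.standard_normal((n, len(spec.items))) * unique_sd[None, :]

    responses = np.empty((n, len(spec.items)), dtype=np.int64)
    for idx, item in enumerate(spec.items):
        responses[:, idx] = np.searchsorted(spec.item_thresholds[item], latent[:, idx])

    index = pd.RangeIndex(n, name="participant_id")
    covariates = pd.DataFrame(
        {
            "age": np.clip(rng.normal(33.0, 11.0, size=n), 18, 75).round(0),
            "gender": rng.choice(["female", "male"], size=n, p=[0.58, 0.42]),
            "iq": rng.normal(100.0, 10.0, size=n).round(1),
        },
        index=index,
    )
    return SyntheticDataset(
        responses=pd.DataFrame(responses, index=index, columns=spec.items),
        covariates=covariates,
        outcomes=pd.DataFrame(index=index),
        true_factor_scores=pd.DataFrame(F, index=index, columns=spec.factors),
        questionnaire_of_item=dict(spec.questionnaire_of_item),
        seed=int(seed),
    )


def conditional_factor_variances(Phi: np.ndarray) -> np.ndarray:
    """Var(f_j | other factors) = 1 / (Phi^{-1})_jj."""
    return 1.0 / np.diag(np.linalg.inv(Phi))


def effect_coefficient(target_f2: float, conditional_var: float, noise_sd: float) -> float:
    """Outcome coefficient b solving the planted signed partial f-squared.

    With y = b f + (other terms independent given the conditioning set) + eps,
    the population partial correlation of y and f given the rest is
    b sqrt(v) / sqrt(b^2 v + sigma^2), hence f2 = b^2 v / sigma^2 and
    b = sign(f2) sigma sqrt(|f2| / v).
    """
    if conditional_var <= 0 or noise_sd <= 0:
        raise InvalidArgumentError("conditional variance and noise_sd must be positive")
    if abs(target_f2) >= 1.0:
        raise InvalidArgumentError("|target f2| must be < 1")
    return float(np.sign(target_f2) * noise_sd * np.sqrt(abs(target_f2) / conditional_var))


def population_f2(coefficient: float, conditional_var: float, noise_sd: float) -> float:
    """Signed population partial f-squared implied by an outcome coefficient."""
    return float(np.sign(coefficient) * coefficient ** 2 * conditional_var / noise_sd ** 2)


def _standardize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariates z-scored; categoricals coded by indicator contrasts
    (largest category as reference) and z-scored."""
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "ifu":
            cols[name] = (col - col.mean()) / col.std(ddof=0)
        else:
            ref = col.value_counts().idxmax()
            for level in sorted(set(col.unique()) - {ref}):
                ind = (col == level).astype(float)
                sd = ind.std(ddof=0)
                cols[f"{name}_{level}"] = (ind - ind.mean()) / sd if sd > 0 else ind * 0.0
    return pd.DataFrame(cols, index=covariates.index)


def attach_cognition(dataset: SyntheticDataset, spec: CognitionSpec,
                     seed: int, *, factor_corr=None) -> SyntheticDataset:
    """Plant a cognitive outcome with the requested partial effect sizes.

    The per-factor coefficients come from :func:`effect_coefficient`
    (closed-form inversion of the population signed f-squared); covariate
    effects are standardised coefficients on z-scored covariate columns.
    ``factor_corr`` should be the planted factor correlation matrix; when
    omitted it is estimated from the stored true factor scores.  Returns the
    same dataset with the outcome column added.
    """
    if dataset.true_factor_scores.empty:
        raise InvalidArgumentError("dataset lacks true factor scores")
    rng = np.random.default_rng(seed)
    Phi_factors = list(dataset.true_factor_scores.columns)
    F = dataset.true_factor_scores.to_numpy()
    if factor_corr is None:
        factor_corr = np.corrcoef(F, rowvar=False) if F.shape[1] > 1 else np.eye(1)
    cond_var = conditional_factor_variances(np.asarray(factor_corr, dtype=float))

    b = np.zeros(len(Phi_factors))
    for factor, f2 in spec.target_f2_per_factor.items():
        if factor not in Phi_factors:
            raise InvalidArgumentError(f"unknown factor {factor!r}")
        j = Phi_factors.index(factor)
        b[j] = effect_coefficient(f2, cond_var[j], spec.noise_sd)

    y = F @ b
    if spec.covariate_effects:
        X = _standardize_covariates(dataset.covariates)
        for cov, coef in spec.covariate_effects.items():
            if cov not in X.columns:
                raise InvalidArgumentError(f"unknown covariate {cov!r}")
            y = y + coef * X[cov].to_numpy()
    y = y + rng.normal(0.0, spec.noise_sd, size=len(y))

    outcomes = dataset.outcomes.copy()
    outcomes[spec.outcome_label] = y
    return SyntheticDataset(
        responses=dataset.responses,
        covariates=dataset.covariates,
        outcomes=outcomes,
        true_factor_scores=dataset.true_factor_scores,
        questionnaire_of_item=dataset.questionnaire_of_item,
        seed=dataset.seed,
        name=dataset.name,
    )


def default_cognition_specs(noise_sd: float = 1.0) -> dict:
    """The two planted outcome models of the default benchmark.

    Model-based planning carries a small negative compulsivity effect
    (f2 = -0.014); mean confidence carries a positive compulsivity effect
    (+0.038, overconfidence) and a negative anxious-depression effect
    (-0.030, underconfidence).  Covariate effects are modest standardised
    coefficients on age, gender and IQ.
    """
    covariate_effects = {"age": -0.10, "iq": 0.10, "gender_male": 0.05}
    return {
        PLANNING: CognitionSpec(
            outcome_label=PLANNING,
            target_f2_per_factor={"CIT": -0.014},
            covariate_effects=covariate_effects,
            noise_sd=noise_sd,
        ),
        CONFIDENCE: CognitionSpec(
            outcome_label=CONFIDENCE,
            target_f2_per_factor={"CIT": 0.038, "AD": -0.030},
            covariate_effects=covariate_effects,
            noise_sd=noise_sd,
        ),
    }


def make_benchmark(n_datasets: int = 3, n: int = 2000, seed: int = 0,
                   spec: LatentSpec | None = None) -> list[SyntheticDataset]:
    """Simulate the default multi-dataset benchmark.

    ``n_datasets`` studies of ``n`` participants each are drawn from the same
    latent spec, every one carrying both cognitive outcomes with the planted
    default effect sizes.  The first dataset plays the discovery role.
    Per-dataset seeds are derived deterministically from ``seed``.
    """
    spec = spec or build_default_spec()
    cog = default_cognition_specs()
    datasets = []
    for i in range(n_datasets):
        child = (seed * 100003 + 7919 * i + 1) % (2 ** 31)
        ds = simulate_responses(spec, n, child)
        ds.name = "discovery" if i == 0 else f"replication_{i}"
        for j, cs in enumerate(cog.values()):
            ds = attach_cognition(ds, cs, (child + 31 * (j + 1)) % (2 ** 31),
                                  factor_corr=spec.factor_corr)
        datasets.append(ds)
    return datasets
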