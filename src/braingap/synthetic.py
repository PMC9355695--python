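"""Synthetic aging-cohort generator.

Emulates the data structure the association pipeline assumes: a
subject-by-variable table of an older-adult cohort with complete
covariates (sex, age, total intracranial volume), a block of
intercorrelated brain-age-gap variables (years, mean zero by
construction, i.e. already bias-corrected against the covariates), and a
set of mixed-type criterion variables (skewed continuous, ordinal-coded,
binary) with per-variable missingness and planted gap associations of
configurable size.

Planted effects are defined on a latent-normal scale: each criterion's
latent score loads on the standardized equal-weight composite of the gap
block with a coefficient chosen so that the latent variable's partial
correlation with each individual gap variable, given the covariates,
equals ``planted_r`` in the population. Monotone shape transforms
(lognormal) and discretization (ordinal/binary thresholding) are applied
afterwards and attenuate the realized Pearson correlation; this is
deliberate and documented rather than corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSpec",
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "apply_missingness",
    "generate_feature_matrix",
    "default_cohort_spec",
]

ROLES = ("covariate", "gap", "criterion")
DISTS = ("normal", "lognormal", "ordinal", "binary")


@dataclass(frozen=True)
class VariableSpec:
    """One criterion variable's generating recipe.

    ``mean``/``sd`` are targets in natural units (ignored for ordinal and
    binary variables, whose scale is the category code). ``planted_r`` is
    the target partial correlation with each gap variable given the
    covariates, defined on the latent-normal scale. ``covariate_loading``
    adds an age component to the latent score so that residualization has
    real work to do; it does not change the partial correlation.
    """

    name: str
    role: str = "criterion"
    dist: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    n_observed: int | None = None
    planted_r: float = 0.0
    expected_sign: int = 1
    levels: int | None = None
    level_probs: tuple[float, ...] | None = None
    prevalence: float | None = None
    shift: float = 0.0
    covariate_loading: float = 0.2

    def validate(self, n_subjects: int, n_covariates: int) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.dist not in DISTS:
            raise ValueError(f"{self.name}: unknown dist {self.dist!r}")
        if not -1 < self.planted_r < 1:
            raise ValueError(f"{self.name}: |planted_r| must be < 1")
        if self.expected_sign not in (-1, 1):
            raise ValueError(f"{self.name}: expected_sign must be +1 or -1")
        n_obs = self.n_observed if self.n_observed is not None else n_subjects
        if not 4 + n_covariates + 2 <= n_obs <= n_subjects:
            raise ValueError(
                f"{self.name}: n_observed={n_obs} outside "
                f"[{4 + n_covariates + 2}, {n_subjects}]"
            )
        if self.dist == "ordinal":
            if self.levels is None or self.levels < 2:
                raise ValueError(f"{self.name}: ordinal needs levels >= 2")
            if self.level_probs is not None:
                if len(self.level_probs) != self.levels:
                    raise ValueError(f"{self.name}: level_probs length mismatch")
                if not np.isclose(sum(self.level_probs), 1.0):
                    raise ValueError(f"{self.name}: level_probs must sum to 1")
        if self.dist == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError(f"{self.name}: binary needs prevalence in (0,1)")
        if self.dist == "lognormal" and self.mean - self.shift <= 0:
            raise ValueError(f"{self.name}: lognormal needs mean - shift > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generating parameters.

    Defaults mirror an older-adult aging cohort: 335 subjects aged 61-82
    (mean 70.5, SD 3.8), 37.9% female, and three bias-corrected
    brain-age-gap variables with SDs of 2.99, 3.71 and 3.17 years and a
    default pairwise intercorrelation of 0.7.
    """

    n_subjects: int = 335
    age_range: tuple[float, float] = (61.0, 82.0)
    age_mean: float = 70.5
    age_sd: float = 3.8
    sex_ratio: float = 127 / 335
    tiv_mean: float = 1475.0
    tiv_sd: float = 130.0
    gap_sds: tuple[float, ...] = (2.99, 3.71, 3.17)
    gap_labels: tuple[str, ...] = ("gap_gm", "gap_wm", "gap_gwm")
    gap_intercorrelation: float = 0.7
    variables: tuple[VariableSpec, ...] = ()
    seed: int = 0

    # number of non-intercept covariate columns (sex, age, age^2, TIV)
    N_COVARIATES = 4

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise ValueError("n_subjects must be >= 20")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must lie strictly in (0, 1)")
        if not 0 <= self.gap_intercorrelation < 1:
            raise ValueError("gap_intercorrelation must lie in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must satisfy min < max")
        if len(self.gap_sds) != len(self.gap_labels):
            raise ValueError("gap_sds and gap_labels lengths differ")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for v in self.variables:
            v.validate(self.n_subjects, self.N_COVARIATES)


@dataclass
class CohortTable:
    """Subject-by-variable rectangle with column roles and metadata."""

    data: pd.DataFrame
    roles: dict[str, str]
    specs: dict[str, VariableSpec] = field(default_factory=dict)
    seed: int | None = None

    def labels(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles.get(c) == role]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def hypothesis_signs(self) -> dict[str, int]:
        return {
            name: spec.expected_sign
            for name, spec in self.specs.items()
            if spec.role == "criterion"
        }

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        path = Path(path)
        self.data.to_csv(path, sep=sep, na_rep="NA", index_label="subject_id")
        meta = {"roles": self.roles, "seed": self.seed,
                "hypotheses": self.hypothesis_signs()}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        roles: dict[str, str] | None = None,
        sep: str = ",",
    ) -> "CohortTable":
        path = Path(path)
        df = pd.read_csv(path, sep=sep, na_values=["NA", ""], index_col=0)
        seed = None
        specs: dict[str, VariableSpec] = {}
        if roles is None:
            meta_path = path.with_suffix(path.suffix + ".meta.json")
            if not meta_path.exists():
                raise ValueError(
                    f"no roles given and no metadata file at {meta_path}"
                )
            meta = json.loads(meta_path.read_text())
            roles, seed = meta["roles"], meta.get("seed")
            # hypothesized directions survive a round trip via metadata
            specs = {
                name: VariableSpec(name=name, role="criterion",
                                   expected_sign=int(sign))
                for name, sign in meta.get("hypotheses", {}).items()
            }
        return cls(data=df, roles=dict(roles), specs=specs, seed=seed)


def _truncated_normal(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _residualize_exact(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw one cohort according to ``spec``; deterministic for fixed seed.

    Covariates are complete; gap columns are exactly mean-zero and
    sample-orthogonal to the covariate design (they represent
    bias-corrected gap estimates) with sample SDs equal to ``gap_sds``.
    Missingness is NOT applied here; see :func:`apply_missingness`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = _truncated_normal(rng, n, spec.age_mean, spec.age_sd, *spec.age_range)
    sex = (rng.random(n) < spec.sex_ratio).astype(float)  # 1 = female
    tiv = rng.normal(spec.tiv_mean, spec.tiv_sd, size=n)
    design = np.column_stack([np.ones(n), sex, age, age**2, tiv])

    k = len(spec.gap_sds)
    c = spec.gap_intercorrelation
    corr = np.full((k, k), c)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded by spec
        raise ValueError(
            f"gap block correlation matrix (r={c}) is not positive-definite"
        ) from err
    raw = rng.standard_normal((n, k)) @ chol.T
    gaps = np.empty_like(raw)
    for j in range(k):
        resid = _residualize_exact(raw[:, j], design)
        gaps[:, j] = spec.gap_sds[j] * _standardize(resid)

    # standardized equal-weight composite of the gap block and its
    # population correlation with each (equicorrelated) member
    composite = _standardize(_standardize(gaps).mean(axis=1)
                             if k > 1 else gaps[:, 0])
    w = np.sqrt((1.0 + (k - 1) * c) / k)
    age_std = _standardize(age)

    columns: dict[str, np.ndarray] = {"sex": sex, "age": age, "tiv": tiv}
    roles = {"sex": "covariate", "age": "covariate", "tiv": "covariate"}
    for j, label in enumerate(spec.gap_labels):
        columns[label] = gaps[:, j]
        roles[label] = "gap"

    specs: dict[str, VariableSpec] = {}
    for var in spec.variables:
        rho = var.planted_r / w
        if not -1 < rho < 1:
            raise ValueError(
                f"{var.name}: planted_r={var.planted_r} infeasible against the "
                f"gap block (composite loading {rho:.3f} outside (-1, 1) at "
                f"intercorrelation {c})"
            )
        noise = rng.standard_normal(n)
        latent = rho * composite + np.sqrt(1 - rho**2) * noise
        full = var.covariate_loading * age_std + latent
        scale = np.sqrt(1.0 + var.covariate_loading**2)
        z = full / scale  # approximately standard normal
        columns[var.name] = _shape_transform(var, z)
        roles[var.name] = var.role
        specs[var.name] = var

    ids = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(columns, index=pd.Index(ids, name="subject_id"))
    return CohortTable(data=df, roles=roles, specs=specs, seed=spec.seed)


def _shape_transform(var: VariableSpec, z: np.ndarray) -> np.ndarray:
    """Map a (near) standard-normal latent onto the variable's scale."""
    if var.dist == "normal":
        return var.mean + var.sd * z
    if var.dist == "lognormal":
        m = var.mean - var.shift
        sigma2 = np.log1p((var.sd / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return var.shift + np.exp(mu + np.sqrt(sigma2) * z)
    if var.dist == "binary":
        return (z > stats.norm.isf(var.prevalence)).astype(float)
    # ordinal: threshold at normal quantiles of the cumulative level
    # probabilities (equal probabilities unless specified)
    probs = (np.full(var.levels, 1.0 / var.levels)
             if var.level_probs is None else np.asarray(var.level_probs))
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, z).astype(float)


def apply_missingness(table: CohortTable, seed: int) -> CohortTable:
    """Mask criterion entries completely at random to exact per-column counts.

    Each criterion column ends with exactly ``n_observed`` non-missing
    entries (per its :class:`VariableSpec`); covariates and gap columns
    are untouched. Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n = len(df)
    for name in table.labels("criterion"):
        var = table.specs.get(name)
        n_obs = n if var is None or var.n_observed is None else var.n_observed
        if n_obs > n:
            raise ValueError(f"{name}: n_observed={n_obs} exceeds cohort size {n}")
        n_miss = n - n_obs
        if n_miss == 0:
            continue
        idx = rng.choice(n, size=n_miss, replace=False)
        df.iloc[idx, df.columns.get_loc(name)] = np.nan
    return CohortTable(data=df, roles=dict(table.roles),
                       specs=dict(table.specs), seed=table.seed)


def generate_feature_matrix(
    n_subjects: int,
    n_features: int,
    age_signal: float,
    seed: int,
    age_range: tuple[float, float] = (61.0, 82.0),
    n_noise_components: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank feature matrix whose best linear age predictor attains
    correlation ~ ``age_signal``; a stand-in for morphometry-derived
    image features.

    Features = one age-loaded component + ``n_noise_components``
    age-independent structured components + small i.i.d. noise.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    if not 0 <= age_signal <= 1:
        raise ValueError("age_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n_subjects)
    a_std = _standardize(ages)
    signal = age_signal * a_std + np.sqrt(1 - age_signal**2) * \
        rng.standard_normal(n_subjects)
    q = min(n_noise_components, n_features - 1)
    comps = np.column_stack([signal] + [rng.standard_normal(n_subjects)
                                        for _ in range(q)])
    loadings = rng.standard_normal((q + 1, n_features))
    matrix = comps @ loadings + 0.1 * rng.standard_normal(
        (n_subjects, n_features))
    return matrix, ages


def default_cohort_spec(seed: int = 0, planted_r: float = 0.0,
                        with_missingness: bool = True) -> CohortSpec:
    """Template cohort: 27 mixed-type criteria of an older-adult health
    battery (socioeconomic, lifestyle, affect, metabolic, laboratory,
    cognitive and time-horizon measures) with realistic per-variable N,
    means, SDs and shapes; all planted effects default to null.

    ``planted_r`` sets a common planted partial correlation on every
    criterion (with its hypothesized sign).
    """
    def v(name, sign, dist="normal", **kw):
        r = planted_r * sign
        return VariableSpec(name=name, role="criterion", dist=dist,
                            planted_r=r, expected_sign=sign, **kw)

    n = 335
    variables = (
        v("years_of_education", -1, mean=14.05, sd=2.88, n_observed=300),
        v("household_income", -1, "lognormal", mean=2376, sd=1259,
          n_observed=221),
        v("mmse", -1, mean=28.5, sd=1.5, n_observed=326),
        v("geriatric_depression", 1, "lognormal", mean=1.15, sd=1.64,
          shift=-0.5, n_observed=327),
        v("cesd_depression", 1, "lognormal", mean=6.42, sd=5.94, shift=-1.0,
          n_observed=327),
        v("smoking_status", 1, "ordinal", levels=4,
          level_probs=(0.48, 0.42, 0.01, 0.09), n_observed=278),
        v("alcohol_frequency", 1, "ordinal", levels=5,
          level_probs=(0.02, 0.18, 0.26, 0.25, 0.29), n_observed=163),
        v("alcohol_amount", 1, "ordinal", levels=3,
          level_probs=(0.76, 0.20, 0.04), n_observed=160),
        v("binge_frequency", 1, "ordinal", levels=4,
          level_probs=(0.74, 0.23, 0.01, 0.02), n_observed=161),
        v("diabetes_diagnosis", 1, "binary", prevalence=34 / 328,
          n_observed=328),
        v("homa_ir", 1, "lognormal", mean=2.61, sd=3.24, n_observed=318),
        v("hba1c", 1, "lognormal", mean=5.58, sd=0.55, shift=4.0,
          n_observed=322),
        v("fasting_glucose", 1, "lognormal", mean=96.4, sd=21.2, shift=60.0,
          n_observed=294),
        v("postload_glucose", 1, "lognormal", mean=110.4, sd=38.2, shift=20.0,
          n_observed=276),
        v("bmi", 1, mean=26.7, sd=3.5, n_observed=327),
        v("diastolic_bp", 1, mean=84.7, sd=10.9, n_observed=281),
        v("systolic_bp", 1, mean=145.5, sd=18.1, n_observed=281),
        v("metabolic_load", 1, "lognormal", mean=0.01, sd=0.14, shift=-0.3,
          n_observed=321),
        v("ggt", 1, "lognormal", mean=30.1, sd=29.1, n_observed=327),
        v("uric_acid", 1, mean=5.48, sd=1.28, n_observed=327),
        v("tnf_alpha", 1, "lognormal", mean=0.82, sd=3.48, shift=-0.02,
          n_observed=307),
        v("digit_symbol", -1, mean=44.9, sd=9.8, n_observed=324),
        v("episodic_memory", -1, mean=0.03, sd=0.34),
        v("working_memory", -1, mean=0.05, sd=0.61),
        v("fluid_intelligence", -1, mean=0.03, sd=0.71),
        v("future_time_perspective", -1, mean=2.65, sd=0.69, n_observed=332),
        v("consideration_future", -1, mean=3.24, sd=0.47),
    )
    if not with_missingness:
        variables = tuple(replace(var, n_observed=None) for var in variables)
    return CohortSpec(n_subjects=n, variables=variables, seed=seed)
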