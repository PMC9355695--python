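"""Directed partial-correlation scans with covariate residualization.

The scan correlates each brain-age-gap variable with each criterion
variable after removing the linear effects of the covariates (by default
sex, age, age^2 and total intracranial volume; age^2 is derived
internally from the age column) from both sides. Degrees of freedom are
reduced by the number of covariates: df = n_pair - 2 - k. Hypotheses are
directed, so one-tailed p-values are computed in the pre-specified
direction of each criterion.

Also provides the eigenvalue-based effective number of independent tests
(Li-Ji), the study-wise significance threshold it implies, and
average-linkage clustering of criterion variables on 1 - |r| distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic import CohortTable

__all__ = [
    "DEFAULT_COVARIATES",
    "HypothesisSpec",
    "AssociationResult",
    "EffectiveTests",
    "residualize",
    "covariate_design",
    "partial_scan",
    "li_ji_meff",
    "corrected_threshold",
    "cluster_criteria",
    "scan_to_frame",
]

DEFAULT_COVARIATES: tuple[str, ...] = ("sex", "age", "age^2", "tiv")


@dataclass(frozen=True)
class HypothesisSpec:
    """Expected effect direction (+1 / -1) per criterion variable."""

    signs: Mapping[str, int]

    def __post_init__(self):
        for name, s in self.signs.items():
            if s not in (-1, 1):
                raise ValueError(f"{name}: expected sign must be +1 or -1, got {s}")

    def sign(self, criterion: str) -> int:
        if criterion not in self.signs:
            raise KeyError(f"no hypothesized direction for {criterion!r}")
        return self.signs[criterion]

    @classmethod
    def from_table(cls, table: CohortTable) -> "HypothesisSpec":
        return cls(signs=table.hypothesis_signs())

    @classmethod
    def read_csv(cls, path: str | Path, sep: str | None = None) -> "HypothesisSpec":
        """Two-column file: criterion, sign in {+, -, +1, -1, 1}."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["criterion", "sign"], skipinitialspace=True)
        if df["criterion"].iloc[0].strip().lower() == "criterion":
            df = df.iloc[1:]
        parse = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}
        signs = {}
        for _, row in df.iterrows():
            token = str(row["sign"]).strip()
            if token not in parse:
                raise ValueError(f"cannot parse hypothesis sign {token!r}")
            signs[str(row["criterion"]).strip()] = parse[token]
        return cls(signs=signs)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"criterion": list(self.signs), "sign": list(self.signs.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AssociationResult:
    """One (gap, criterion) pair of the directed scan."""

    gap: str
    criterion: str
    n_pair: int
    k_covariates: int
    r: float
    df: int
    t: float
    p_one: float
    p_two: float
    expected_sign: int


@dataclass(frozen=True)
class EffectiveTests:
    """Effective number of independent tests among correlated variables."""

    m_raw: int
    eigenvalues: np.ndarray
    m_eff_raw: float

    @property
    def m_eff(self) -> int:
        return int(round(self.m_eff_raw))


def residualize(
    values: np.ndarray,
    covariates: np.ndarray | None,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Residuals of ``values`` on ``covariates`` (intercept always added).

    The regression is fit on the rows where ``values`` is observed;
    missing entries stay missing. With ``covariates=None`` the residuals
    are simply the mean-centered values.
    """
    y = np.asarray(values, dtype=float)
    obs = np.isfinite(y)
    n_obs = int(obs.sum())
    if covariates is None:
        covariates = np.empty((len(y), 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n_obs), C[obs]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        labels = list(names) if names is not None else [
            f"column {j}" for j in range(C.shape[1])]
        bad = _collinear_columns(X, labels)
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - X @ beta
    return out


def _collinear_columns(X: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Name non-intercept columns that do not increase the design's rank."""
    bad, kept = [], X[:, :1]
    for j in range(1, X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            bad.append(labels[j - 1])
        else:
            kept = trial
    return bad


def covariate_design(
    table: CohortTable, covariate_labels: Sequence[str] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Assemble the n x k covariate matrix (no intercept column).

    The label ``"age^2"`` (or ``"age2"``) is derived by squaring the age
    column rather than read from the table, so the linear and quadratic
    age terms can never disagree.
    """
    cols, names = [], []
    for label in covariate_labels:
        if label in ("age^2", "age2") and label not in table.data.columns:
            cols.append(table.data["age"].to_numpy(dtype=float) ** 2)
        else:
            cols.append(table.data[label].to_numpy(dtype=float))
        names.append(label)
    mat = np.column_stack(cols) if cols else np.empty((table.n_subjects, 0))
    if not np.isfinite(mat).all():
        raise ValueError("covariate columns must be complete (no missing)")
    return mat, names


def _pair_statistics(r: float, n_pair: int, k: int, sign: int):
    df = n_pair - 2 - k
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p_one = float(stats.t.sf(sign * t, df))
    p_two = 2.0 * min(p_one, 1.0 - p_one)
    return r, df, float(t), p_one, p_two


def partial_scan(
    table: CohortTable,
    hypotheses: HypothesisSpec | None = None,
    gap_labels: Sequence[str] | None = None,
    criterion_labels: Sequence[str] | None = None,
    covariate_labels: Sequence[str] = DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Directed partial-correlation scan over all (gap, criterion) pairs.

    Each pair is analyzed on its own pairwise-complete rows: the rows
    where both members are observed, with residualization refit there.
    Pairs with fewer than k + 4 complete rows are excluded with a
    warning. Raises before any computation if a scanned criterion lacks
    a hypothesized direction.
    """
    gap_labels = list(gap_labels or table.labels("gap"))
    criterion_labels = list(criterion_labels or table.labels("criterion"))
    if hypotheses is None:
        hypotheses = HypothesisSpec.from_table(table)
    for crit in criterion_labels:
        hypotheses.sign(crit)  # fail fast on missing hypotheses
    C, cov_names = covariate_design(table, covariate_labels)
    k = C.shape[1]

    results: list[AssociationResult] = []
    for gap in gap_labels:
        g = table.data[gap].to_numpy(dtype=float)
        for crit in criterion_labels:
            y = table.data[crit].to_numpy(dtype=float)
            rows = np.isfinite(g) & np.isfinite(y)
            n_pair = int(rows.sum())
            if n_pair < k + 4:
                warnings.warn(
                    f"pair ({gap}, {crit}) excluded: only {n_pair} complete "
                    f"rows (< {k + 4})"
                )
                continue
            g_res = residualize(g[rows], C[rows], cov_names)
            y_res = residualize(y[rows], C[rows], cov_names)
            r = float(np.corrcoef(g_res, y_res)[0, 1])
            sign = hypotheses.sign(crit)
            r, df, t, p_one, p_two = _pair_statistics(r, n_pair, k, sign)
            results.append(AssociationResult(
                gap=gap, criterion=crit, n_pair=n_pair, k_covariates=k,
                r=r, df=df, t=t, p_one=p_one, p_two=p_two,
                expected_sign=sign))
    return results


def scan_to_frame(
    results: Sequence[AssociationResult],
    nominal_alpha: float = 0.05,
    studywise_threshold: float = 0.001,
) -> pd.DataFrame:
    """Tidy one-row-per-pair table of a scan's results."""
    df = pd.DataFrame([vars(res) for res in results])
    df["significant_nominal"] = df["p_one"] < nominal_alpha
    df["significant_studywise"] = df["p_one"] < studywise_threshold
    return df


def li_ji_meff(correlation_matrix: np.ndarray) -> EffectiveTests:
    """Effective number of independent tests from the eigenvalues of a
    correlation matrix: sum over eigenvalues of 1(|e| >= 1) plus the
    fractional part of |e|.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    eig = np.abs(np.linalg.eigvalsh((R + R.T) / 2.0))
    m_eff_raw = float(np.sum((eig >= 1.0) + (eig - np.floor(eig))))
    return EffectiveTests(m_raw=R.shape[0], eigenvalues=eig,
                          m_eff_raw=m_eff_raw)


def corrected_threshold(
    m_eff_gaps: float, m_eff_criteria: float, alpha: float = 0.05
) -> float:
    """Study-wise threshold: alpha / (effective gap tests x effective
    criterion tests)."""
    if m_eff_gaps < 1 or m_eff_criteria < 1:
        raise ValueError("effective test counts must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (m_eff_gaps * m_eff_criteria)


def cluster_criteria(
    correlation_matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    cut_distance: float | None = None,
):
    """Average-linkage agglomeration of variables on 1 - |r| distance.

    Returns ``(linkage_matrix, flat_labels)``; flat labels are None
    unless ``cut_distance`` is given. Ties break deterministically by
    input (label) order.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    if not np.isfinite(R).all():
        raise ValueError("correlation matrix contains missing entries")
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    flat = None
    if cut_distance is not None:
        flat = fcluster(Z, t=cut_distance, criterion="distance")
    return Z, flat
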