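"""Grouped-permutation aggregate evidence for directed association scans.

The null model permutes the subject rows of the brain-age-gap block
jointly, leaving the criterion block (and its missingness pattern) in
place. Correlations within the gap block and within the criterion block
are therefore preserved exactly in every replicate, while gap-criterion
dependence is destroyed. All variables are residualized on the
covariates once, before permutation; each permuted pair is then
correlated over its own pairwise-complete rows, so per-variable N is
preserved under the null.

Four aggregate statistics summarize a scan against its permutation
null: the count of hypothesis-consistent effect directions, the count of
nominally significant one-tailed tests, the Fisher-z mean correlation
(sign-aligned so that hypothesis-consistent effects are positive), and
the inflation factor lambda (median chi-square(1) quantile of the
one-tailed p-values divided by 0.4549364, the chi-square(1) median).
Permutation p-values are the proportion of null replicates with an
equal-or-larger statistic; an add-one smoothed convention is available
and avoids reporting exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    DEFAULT_COVARIATES,
    AssociationResult,
    HypothesisSpec,
    covariate_design,
    residualize,
    _pair_statistics,
)
from .synthetic import CohortTable

__all__ = [
    "CHI2_MEDIAN_1DF",
    "PermutationConfig",
    "NullDistribution",
    "EvidenceSummary",
    "scan_residualized",
    "grouped_permute",
    "count_consistent",
    "mean_fisher_r",
    "chisq_from_p",
    "inflation_lambda",
    "permutation_pvalue",
    "evidence_summary",
    "qq_envelope",
    "fwer_at_threshold",
]

#: Median of the chi-square distribution with one degree of freedom
#: (the chi-square quantile corresponding to p = 0.5).
CHI2_MEDIAN_1DF = 0.4549364


@dataclass(frozen=True)
class PermutationConfig:
    B: int = 10_000
    seed: int = 0
    nominal_alpha: float = 0.05
    studywise_threshold: float = 0.001
    p_value_convention: str = "proportion"  # or "add_one"
    retain_matrices: bool = True

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        for name in ("nominal_alpha", "studywise_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p_value_convention not in ("proportion", "add_one"):
            raise ValueError("p_value_convention must be proportion or add_one")


def _aggregate(signed_r: np.ndarray, p_one: np.ndarray,
               nominal_alpha: float) -> dict[str, np.ndarray]:
    """Per-replicate aggregates over the last axis (tests).

    ``signed_r``/``p_one`` have shape (B, m): sign-aligned correlations
    and one-tailed p-values of m tests per replicate.
    """
    lam = (np.median(stats.chi2.isf(np.clip(p_one, 1e-300, 1.0), 1), axis=-1)
           / CHI2_MEDIAN_1DF)
    return {
        "n_consistent": (signed_r > 0).sum(axis=-1),
        "n_nominal": (p_one < nominal_alpha).sum(axis=-1),
        "mean_r": np.tanh(np.mean(np.arctanh(signed_r), axis=-1)),
        "lambda": lam,
        "min_p": p_one.min(axis=-1),
    }


@dataclass
class NullDistribution:
    """Permutation replicates of the full scan's statistics.

    ``r`` and ``p_one`` (shape B x n_gaps x n_criteria) are retained only
    when the configuration asks for them; per-replicate aggregates (for
    the pooled test set and for each gap variable separately) are always
    available.
    """

    B: int
    seed: int
    gap_labels: list[str]
    criterion_labels: list[str]
    signs: np.ndarray
    df: np.ndarray  # per (gap, criterion) pair, shape n_gaps x n_criteria
    aggregates: dict[str, dict[str, np.ndarray]]
    config: PermutationConfig
    r: np.ndarray | None = None
    p_one: np.ndarray | None = None

    def p_matrix(self, gap: str | None = None) -> np.ndarray:
        """Per-replicate one-tailed p-values, shape (B, m)."""
        if self.p_one is None:
            raise ValueError(
                "per-replicate p matrices were not retained; re-run "
                "grouped_permute with retain_matrices=True"
            )
        if gap is None:
            return self.p_one.reshape(self.B, -1)
        j = self.gap_labels.index(gap)
        return self.p_one[:, j, :]


def _prefit_residuals(table: CohortTable, gap_labels, criterion_labels,
                      covariate_labels):
    """Residualize gap and criterion columns once, each on its own
    observed rows."""
    C, cov_names = covariate_design(table, covariate_labels)
    G = np.column_stack([
        residualize(table.data[g].to_numpy(dtype=float), C, cov_names)
        for g in gap_labels])
    if not np.isfinite(G).all():
        raise ValueError("gap block must be complete (no missing values)")
    crit = {c: residualize(table.data[c].to_numpy(dtype=float), C, cov_names)
            for c in criterion_labels}
    return G, crit, C.shape[1]


def scan_residualized(
    table: CohortTable,
    hypotheses: HypothesisSpec | None = None,
    gap_labels: Sequence[str] | None = None,
    criterion_labels: Sequence[str] | None = None,
    covariate_labels: Sequence[str] = DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Scan with a single up-front residualization per variable.

    This is the observed counterpart of the permutation null: variables
    are residualized once on their own observed rows, then each pair is
    correlated over its pairwise-complete rows. It differs from
    :func:`braingap.association.partial_scan` (which refits
    residualization per pair) only when criteria have missing entries.
    """
    gap_labels = list(gap_labels or table.labels("gap"))
    criterion_labels = list(criterion_labels or table.labels("criterion"))
    if hypotheses is None:
        hypotheses = HypothesisSpec.from_table(table)
    G, crit, k = _prefit_residuals(table, gap_labels, criterion_labels,
                                   covariate_labels)
    results = []
    for j, gap in enumerate(gap_labels):
        for c in criterion_labels:
            y = crit[c]
            rows = np.isfinite(y)
            n_pair = int(rows.sum())
            r = float(np.corrcoef(G[rows, j], y[rows])[0, 1])
            sign = hypotheses.sign(c)
            r, df, t, p_one, p_two = _pair_statistics(r, n_pair, k, sign)
            results.append(AssociationResult(
                gap=gap, criterion=c, n_pair=n_pair, k_covariates=k,
                r=r, df=df, t=t, p_one=p_one, p_two=p_two,
                expected_sign=sign))
    return results


def grouped_permute(
    table: CohortTable,
    config: PermutationConfig,
    hypotheses: HypothesisSpec | None = None,
    gap_labels: Sequence[str] | None = None,
    criterion_labels: Sequence[str] | None = None,
    covariate_labels: Sequence[str] = DEFAULT_COVARIATES,
) -> NullDistribution:
    """B grouped permutations of the gap block, rescanning each time.

    Every replicate applies one row permutation jointly to all gap
    columns and recomputes the full directed scan on the residualized
    variables.
    """
    gap_labels = list(gap_labels or table.labels("gap"))
    criterion_labels = list(criterion_labels or table.labels("criterion"))
    if hypotheses is None:
        hypotheses = HypothesisSpec.from_table(table)
    signs = np.array([hypotheses.sign(c) for c in criterion_labels])
    G, crit, k = _prefit_residuals(table, gap_labels, criterion_labels,
                                   covariate_labels)
    n, ng = G.shape
    nc = len(criterion_labels)
    B = config.B

    rng = np.random.default_rng(config.seed)
    perms = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)

    r_null = np.empty((B, ng, nc))
    p_null = np.empty((B, ng, nc))
    df_pair = np.empty((ng, nc), dtype=int)
    for jc, c in enumerate(criterion_labels):
        y = crit[c]
        mask = np.isfinite(y)
        idx = np.where(mask)[0]
        yc = y[idx] - y[idx].mean()
        y_ss = float(yc @ yc)
        n_pair = len(idx)
        df = n_pair - 2 - k
        df_pair[:, jc] = df
        # permuted gap rows aligned to this criterion's observed rows
        A = G[perms[:, idx], :]                      # (B, n_pair, ng)
        A = A - A.mean(axis=1, keepdims=True)
        num = np.einsum("bnk,n->bk", A, yc)
        den = np.sqrt(np.einsum("bnk,bnk->bk", A, A) * y_ss)
        r = np.clip(num / den, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        r_null[:, :, jc] = r
        p_null[:, :, jc] = stats.t.sf(signs[jc] * t, df)

    signed = signs[None, None, :] * r_null
    aggregates = {"pooled": _aggregate(signed.reshape(B, -1),
                                       p_null.reshape(B, -1),
                                       config.nominal_alpha)}
    for j, gap in enumerate(gap_labels):
        aggregates[gap] = _aggregate(signed[:, j, :], p_null[:, j, :],
                                     config.nominal_alpha)
    return NullDistribution(
        B=B, seed=config.seed, gap_labels=gap_labels,
        criterion_labels=criterion_labels, signs=signs, df=df_pair,
        aggregates=aggregates, config=config,
        r=r_null if config.retain_matrices else None,
        p_one=p_null if config.retain_matrices else None,
    )


def count_consistent(results: Sequence[AssociationResult],
                     hypotheses: HypothesisSpec) -> int:
    """Number of pairs whose partial correlation has the hypothesized
    sign; r exactly 0 counts as inconsistent."""
    return sum(hypotheses.sign(res.criterion) * res.r > 0 for res in results)


def mean_fisher_r(results: Sequence[AssociationResult],
                  hypotheses: HypothesisSpec) -> float:
    """Fisher-z average of sign-aligned correlations, back-transformed."""
    rs = np.array([hypotheses.sign(res.criterion) * res.r for res in results])
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("cannot Fisher-average a correlation of magnitude 1")
    return float(np.tanh(np.mean(np.arctanh(rs))))


def chisq_from_p(p, min_p: float | None = None):
    """Chi-square(1) quantile with upper-tail probability ``p``.

    p = 0 (possible for permutation p-values under the plain proportion
    convention) is capped at ``min_p`` — use 1/(2B) — with a warning.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if min_p is None:
            raise ValueError("p = 0 needs a cap; pass min_p (e.g. 1/(2B))")
        warnings.warn(f"p = 0 capped at {min_p} before chi-square conversion")
        p = np.where(p == 0, min_p, p)
    out = stats.chi2.isf(p, 1)
    return float(out) if out.ndim == 0 else out


def inflation_lambda(p_values, min_p: float | None = None) -> float:
    """Inflation factor: median chi-square(1) quantile of the p-values
    over the chi-square(1) median (0.4549364). Even-length medians are
    midpoint averages."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    return float(np.median(chisq_from_p(p, min_p)) / CHI2_MEDIAN_1DF)


def permutation_pvalue(observed_stat: float, null_stats: np.ndarray,
                       config: PermutationConfig | None = None) -> float:
    """Proportion of null replicates with a statistic >= the observed one
    (ties count); the add-one convention reports (count + 1)/(B + 1)."""
    convention = config.p_value_convention if config else "proportion"
    null_stats = np.asarray(null_stats, dtype=float)
    count = int((null_stats >= observed_stat).sum())
    if convention == "add_one":
        return (count + 1) / (len(null_stats) + 1)
    return count / len(null_stats)


@dataclass
class EvidenceSummary:
    """Observed aggregate statistics with their permutation p-values.

    ``pooled`` covers all gap x criterion tests; ``per_gap`` holds the
    same decomposition restricted to each gap variable's tests.
    """

    n_tests: int
    pooled: dict[str, dict[str, float]]
    per_gap: dict[str, dict[str, dict[str, float]]]
    fwer_at_threshold: float
    B: int
    seed: int
    config: PermutationConfig

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "pooled": self.pooled,
            "per_gap": self.per_gap,
            "fwer_at_threshold": self.fwer_at_threshold,
            "B": self.B,
            "seed": self.seed,
            "config": {
                "B": self.config.B,
                "seed": self.config.seed,
                "nominal_alpha": self.config.nominal_alpha,
                "studywise_threshold": self.config.studywise_threshold,
                "p_value_convention": self.config.p_value_convention,
            },
        }


def _observed_block(results: Sequence[AssociationResult],
                    hypotheses: HypothesisSpec,
                    null_block: Mapping[str, np.ndarray],
                    config: PermutationConfig) -> dict[str, dict[str, float]]:
    signed = np.array([hypotheses.sign(res.criterion) * res.r
                       for res in results])
    p_one = np.array([res.p_one for res in results])
    observed = {
        "n_consistent": float((signed > 0).sum()),
        "n_nominal": float((p_one < config.nominal_alpha).sum()),
        "mean_r": mean_fisher_r(results, hypotheses),
        "lambda": inflation_lambda(p_one),
    }
    return {
        stat: {
            "observed": observed[stat],
            "permutation_p": permutation_pvalue(observed[stat],
                                                null_block[stat], config),
        }
        for stat in observed
    }


def evidence_summary(
    observed_results: Sequence[AssociationResult],
    null: NullDistribution,
    hypotheses: HypothesisSpec | None = None,
    config: PermutationConfig | None = None,
) -> EvidenceSummary:
    """Aggregate-evidence summary: observed counts, mean correlation and
    lambda (pooled and per gap variable) with permutation p-values, plus
    the empirical FWER at the study-wise threshold."""
    config = config or null.config
    if hypotheses is None:
        hypotheses = HypothesisSpec(
            signs={c: int(s) for c, s in
                   zip(null.criterion_labels, null.signs)})
    expected = {(g, c) for g in null.gap_labels for c in null.criterion_labels}
    got = {(res.gap, res.criterion) for res in observed_results}
    if expected != got:
        raise ValueError("observed scan and null cover different test sets")

    pooled = _observed_block(observed_results, hypotheses,
                             null.aggregates["pooled"], config)
    per_gap = {}
    for gap in null.gap_labels:
        sub = [res for res in observed_results if res.gap == gap]
        per_gap[gap] = _observed_block(sub, hypotheses, null.aggregates[gap],
                                       config)
    return EvidenceSummary(
        n_tests=len(expected),
        pooled=pooled,
        per_gap=per_gap,
        fwer_at_threshold=fwer_at_threshold(null, config.studywise_threshold),
        B=null.B,
        seed=null.seed,
        config=config,
    )


def qq_envelope(observed_p: np.ndarray,
                null: NullDistribution | np.ndarray,
                gap: str | None = None) -> pd.DataFrame:
    """Rank-wise QQ data: observed p-values sorted from largest to
    smallest against the mean and 5th/95th percentile of the null order
    statistics, on the raw and -log10 scales."""
    null_p = null.p_matrix(gap) if isinstance(null, NullDistribution) else \
        np.asarray(null, dtype=float)
    observed_p = np.asarray(observed_p, dtype=float)
    m = null_p.shape[1]
    if observed_p.shape != (m,):
        raise ValueError(f"expected {m} observed p-values")
    null_sorted = np.sort(null_p, axis=1)[:, ::-1]  # descending per replicate
    expected_mean = null_sorted.mean(axis=0)
    q05, q95 = np.percentile(null_sorted, [5, 95], axis=0)
    obs_sorted = np.sort(observed_p)[::-1]
    df = pd.DataFrame({
        "rank": np.arange(1, m + 1),
        "observed_p": obs_sorted,
        "expected_mean": expected_mean,
        "q05": q05,
        "q95": q95,
    })
    for col in ("observed_p", "expected_mean", "q05", "q95"):
        df[f"neglog10_{col}"] = -np.log10(np.clip(df[col], 1e-300, None))
    return df


def fwer_at_threshold(null: NullDistribution, threshold: float) -> float:
    """Fraction of null replicates whose smallest one-tailed p-value
    falls below ``threshold``: the family-wise error rate of declaring
    any test significant at that threshold."""
    min_p = null.aggregates["pooled"]["min_p"]
    return float(np.mean(min_p < threshold))
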