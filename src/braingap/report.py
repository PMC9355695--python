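"""Descriptive statistics and end-to-end pipeline orchestration.

``run_pipeline`` sequences the full analysis on one cohort table:
descriptives, the directed partial-correlation scan, the effective
number of independent tests with its corrected threshold, the grouped
permutation null with aggregate-evidence summary, QQ envelope data and
plot, and a sensitivity power table. Every statistical output embeds
the master seed and a hash of the configuration, so a rerun with the
same config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .association import (
    DEFAULT_COVARIATES,
    HypothesisSpec,
    corrected_threshold,
    li_ji_meff,
    partial_scan,
    scan_to_frame,
)
from .permutation import (
    PermutationConfig,
    evidence_summary,
    grouped_permute,
    qq_envelope,
    scan_residualized,
)
from .power import power_table
from .synthetic import CohortTable, apply_missingness, default_cohort_spec, \
    generate_cohort

__all__ = ["RunConfig", "describe", "run_pipeline"]

logger = logging.getLogger("braingap")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "braingap_results"
    cohort_csv: str | None = None      # None -> simulate the default cohort
    hypotheses_csv: str | None = None  # None -> signs from cohort metadata
    covariate_labels: tuple[str, ...] = DEFAULT_COVARIATES
    gap_labels: tuple[str, ...] | None = None
    criterion_labels: tuple[str, ...] | None = None
    seed: int = 0
    B: int = 10_000
    nominal_alpha: float = 0.05
    studywise_threshold: float = 0.001
    p_value_convention: str = "proportion"
    planted_r: float = 0.0             # simulated cohorts only
    power_n: tuple[int, ...] = (160, 335)
    power_r_max: float = 0.4
    power_alpha: float = 0.05
    power_tails: str = "one"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariate_labels", "gap_labels", "criterion_labels",
                    "power_n"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def describe(table: CohortTable) -> pd.DataFrame:
    """Per-variable descriptive statistics on observed values only.

    Quartiles use linear interpolation between order statistics;
    skewness is the standardized third moment and kurtosis the excess
    (standardized fourth moment minus 3); both are undefined (NaN) for
    constant columns.
    """
    rows = []
    for name in table.data.columns:
        x = table.data[name].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            raise ValueError(f"{name}: no observed values")
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        constant = sd == 0.0
        rows.append({
            "variable": name,
            "role": table.roles.get(name, ""),
            "N": len(x),
            "mean": float(np.mean(x)),
            "sd": sd,
            "min": float(x.min()),
            "max": float(x.max()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "skewness": np.nan if constant else float(stats.skew(x)),
            "excess_kurtosis": np.nan if constant or len(x) < 4
            else float(stats.kurtosis(x)),
        })
    return pd.DataFrame(rows).set_index("variable")


def _write_csv(df: pd.DataFrame, path: Path, stamp: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all outputs under ``out_dir``.

    Returns a dict of the in-memory results (table, scan frame, evidence
    summary, QQ data, power table, output paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config_sha={config.config_hash()}"
    handler = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("braingap %s on python %s; %s", __version__,
                    platform.python_version(), stamp)

        if config.cohort_csv is not None:
            table = CohortTable.read_csv(config.cohort_csv)
        else:
            spec = default_cohort_spec(seed=config.seed,
                                       planted_r=config.planted_r)
            table = apply_missingness(generate_cohort(spec),
                                      seed=spec.seed + 1)
            table.write_csv(out / "cohort.csv")
        if config.hypotheses_csv is not None:
            hypotheses = HypothesisSpec.read_csv(config.hypotheses_csv)
        else:
            hypotheses = HypothesisSpec.from_table(table)
            if not hypotheses.signs:
                raise ValueError(
                    "no hypothesis directions available: pass hypotheses_csv "
                    "or a cohort with variable metadata")
        gap_labels = list(config.gap_labels or table.labels("gap"))
        criterion_labels = list(config.criterion_labels
                                or table.labels("criterion"))
        for crit in criterion_labels:
            hypotheses.sign(crit)
        logger.info("cohort: %d subjects, %d gaps, %d criteria",
                    table.n_subjects, len(gap_labels), len(criterion_labels))

        descriptives = describe(table)
        _write_csv(descriptives, out / "descriptives.csv", stamp)

        results = partial_scan(table, hypotheses, gap_labels,
                               criterion_labels, config.covariate_labels)
        crit_corr = table.data[criterion_labels].corr().to_numpy()
        gap_corr = table.data[gap_labels].corr().to_numpy()
        meff_crit = li_ji_meff(crit_corr)
        meff_gap = li_ji_meff(gap_corr)
        threshold = corrected_threshold(meff_gap.m_eff, meff_crit.m_eff,
                                        config.nominal_alpha)
        scan_frame = scan_to_frame(results, config.nominal_alpha,
                                   config.studywise_threshold)
        _write_csv(scan_frame, out / "scan.csv", stamp, index=False)
        logger.info("m_eff: gaps %d, criteria %d -> corrected threshold %.6f",
                    meff_gap.m_eff, meff_crit.m_eff, threshold)

        perm_config = PermutationConfig(
            B=config.B, seed=config.seed,
            nominal_alpha=config.nominal_alpha,
            studywise_threshold=config.studywise_threshold,
            p_value_convention=config.p_value_convention)
        observed = scan_residualized(table, hypotheses, gap_labels,
                                     criterion_labels,
                                     config.covariate_labels)
        null = grouped_permute(table, perm_config, hypotheses, gap_labels,
                               criterion_labels, config.covariate_labels)
        summary = evidence_summary(observed, null, hypotheses, perm_config)
        evidence = summary.to_dict()
        evidence["stamp"] = stamp
        evidence["effective_tests"] = {
            "criteria": {"m_raw": meff_crit.m_raw, "m_eff": meff_crit.m_eff,
                         "m_eff_raw": meff_crit.m_eff_raw},
            "gaps": {"m_raw": meff_gap.m_raw, "m_eff": meff_gap.m_eff,
                     "m_eff_raw": meff_gap.m_eff_raw},
            "corrected_threshold": threshold,
        }
        (out / "evidence.json").write_text(json.dumps(evidence, indent=1))

        qq_frames = {}
        for gap in gap_labels:
            obs_p = np.array([res.p_one for res in observed
                              if res.gap == gap])
            qq = qq_envelope(obs_p, null, gap=gap)
            _write_csv(qq, out / f"qq_{gap}.csv", stamp, index=False)
            qq_frames[gap] = qq
        _plot_qq(qq_frames, out / "qq_plot")
        np.savetxt(out / "null_min_p.txt",
                   null.aggregates["pooled"]["min_p"],
                   header=stamp)

        r_grid = np.round(np.arange(0.0, config.power_r_max + 1e-9, 0.01), 2)
        ptable = power_table(config.power_n, r_grid, config.power_alpha,
                             config.power_tails)
        _write_csv(ptable, out / "power.csv", stamp)

        logger.info("pooled evidence: %s", json.dumps(evidence["pooled"]))
        return {
            "table": table,
            "scan": scan_frame,
            "evidence": evidence,
            "qq": qq_frames,
            "power": ptable,
            "out_dir": out,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def _plot_qq(qq_frames: dict[str, pd.DataFrame], stem: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(qq_frames)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (gap, qq) in zip(axes[0], qq_frames.items()):
        x = qq["neglog10_expected_mean"]
        ax.fill_between(x, qq["neglog10_q95"], qq["neglog10_q05"],
                        color="0.85", label="5th-95th percentile")
        ax.plot(x, x, color="k", lw=1, label="expected mean")
        ax.plot(x, qq["neglog10_observed_p"], "o", ms=4, color="tab:blue",
                label="observed")
        ax.set_xlabel("expected $-\\log_{10} p$")
        ax.set_ylabel("observed $-\\log_{10} p$")
        ax.set_title(gap)
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    for ext in ("svg", "png"):
        fig.savefig(f"{stem}.{ext}", dpi=150)
    plt.close(fig)
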