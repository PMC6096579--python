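"""Per-nucleus records and the statistical layer.

Covers the tests used for stage-wise morphometric comparisons in early
embryos: one-sample Student's t against theoretical spot counts (24 for the
channel-A satellite family, 12 for channel B, as counted on metaphase
spreads) or against d_max = 0; two-sample Kolmogorov-Smirnov between
stages; ordinary linear models with a stage factor and one covariate plus
Shapiro-Wilk / Bartlett diagnostics; and Fisher's exact test for binary
annotation frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "NucleusRecord",
    "ModelSummary",
    "TTestResult",
    "measure_nucleus",
    "one_sample_t",
    "ks_two_sample",
    "fit_group_model",
    "compare_binary_frequencies",
]

STAGES = ("2-cell", "4-cell", "early-8-cell", "late-8-cell", "16-cell")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass
class NucleusRecord:
    """One row of the per-nucleus results table."""

    embryo_id: str
    nucleus_id: int
    stage: str
    nuclear_volume_um3: float
    channels: dict[str, dict[str, float]] = field(default_factory=dict)
    n_npb: int | None = None
    n_npb_associated: int | None = None
    npb_ratio: float | None = None
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nuclear_volume_um3 <= 0:
            raise ValueError("nuclear volume must be positive")

    def as_series(self) -> pd.Series:
        flat: dict[str, object] = {
            "embryo_id": self.embryo_id,
            "nucleus_id": self.nucleus_id,
            "stage": self.stage,
            "nuclear_volume_um3": self.nuclear_volume_um3,
            "n_npb": self.n_npb,
            "n_npb_associated": self.n_npb_associated,
            "npb_ratio": self.npb_ratio,
        }
        for ch, metrics in self.channels.items():
            for k, v in metrics.items():
                flat[f"{ch}_{k}"] = v
        flat["missing"] = ";".join(self.missing)
        return pd.Series(flat)


def measure_nucleus(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    stage: str,
    embryo_id: str = "",
    nucleus_id: int = 0,
    channel_metrics: dict[str, dict[str, float]] | None = None,
    npb_totals: tuple[int, int] | None = None,
) -> NucleusRecord:
    """Assemble a NucleusRecord; absent analyses are flagged, not fatal.

    ``channel_metrics`` maps channel name -> metrics dict (spot counts,
    volumes, d_max, polarity results...); ``npb_totals`` is
    (n_npb, n_associated).
    """
    volume = float(np.asarray(mask, dtype=bool).sum()) * float(np.prod(spacing))
    missing = []
    if not channel_metrics:
        missing.append("channels")
    rec = NucleusRecord(
        embryo_id=embryo_id,
        nucleus_id=nucleus_id,
        stage=stage,
        nuclear_volume_um3=volume,
        channels=channel_metrics or {},
    )
    if npb_totals is not None:
        n_npb, n_assoc = npb_totals
        rec.n_npb = n_npb
        rec.n_npb_associated = n_assoc
        rec.npb_ratio = n_assoc / n_npb if n_npb else 0.0
    else:
        missing.append("npb")
    for ch, metrics in rec.channels.items():
        for key in ("d_max", "polarity_p"):
            if key not in metrics:
                missing.append(f"{ch}.{key}")
    rec.missing = missing
    return rec


def one_sample_t(
    values: Sequence[float] | None = None,
    mu0: float = 0.0,
    alternative: str = "two-sided",
    *,
    n: int | None = None,
    mean: float | None = None,
    sd: float | None = None,
) -> TTestResult:
    """One-sample Student's t against mu0, from raw values or (n, mean, sd).

    The summary form allows recomputing published table statistics (e.g.
    observed spot counts vs the 24/12 expected from metaphase spreads)
    without the raw data.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError("need at least 2 values")
        if values.std(ddof=1) == 0:
            raise ValueError("zero variance")
        res = sps.ttest_1samp(values, mu0, alternative=alternative)
        return TTestResult(float(res.statistic), values.size - 1, float(res.pvalue))
    if n is None or mean is None or sd is None:
        raise ValueError("provide either raw values or all of n, mean, sd")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("zero variance")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TTestResult(float(t), df, float(p))


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModelSummary:
    """OLS fit with a categorical stage factor and one numeric covariate."""

    formula: str
    params: pd.Series
    pvalues: pd.Series
    normality_p: float
    homogeneity_p: float
    nobs: int

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "params": self.params.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "normality_p": self.normality_p,
            "homogeneity_p": self.homogeneity_p,
            "nobs": self.nobs,
        }


def fit_group_model(
    records: pd.DataFrame,
    response: str,
    covariate: str,
    stage_col: str = "stage",
) -> ModelSummary:
    """lm(response ~ stage + covariate) with normality/homogeneity checks.

    Residual normality via Shapiro-Wilk, variance homogeneity across stages
    via Bartlett's test (both reported, not enforced).
    """
    levels = records[stage_col].unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 stage levels")
    counts = records.groupby(stage_col).size()
    if (counts < 3).any():
        warnings.warn(f"fewer than 3 records in some stages: {counts.to_dict()}")
    formula = f"{response} ~ C({stage_col}) + {covariate}"
    fit = smf.ols(formula, data=records).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    shapiro_p = float(sps.shapiro(fit.resid).pvalue)
    groups = [g[response].to_numpy() for _, g in records.groupby(stage_col)]
    bartlett_p = float(sps.bartlett(*groups).pvalue)
    return ModelSummary(formula, fit.params, fit.pvalues, shapiro_p, bartlett_p,
                        int(fit.nobs))


def compare_binary_frequencies(
    table: pd.DataFrame,
    parameter: str,
    stage_a: str,
    stage_b: str,
    stage_col: str = "stage",
    method: str = "fisher",
) -> float:
    """p value for a difference in presence frequency between two stages.

    ``table`` holds one row per nucleus with binary (0/1) annotation
    columns.  Default is Fisher's exact test on the 2x2 contingency table;
    ``method="chi2"`` uses the chi-square test with continuity correction.
    """
    if parameter not in table.columns:
        raise KeyError(f"parameter {parameter!r} not in annotation table")
    for s in (stage_a, stage_b):
        if not (table[stage_col] == s).any():
            raise ValueError(f"stage {s!r} absent from table")
    cont = np.zeros((2, 2), dtype=int)
    for i, s in enumerate((stage_a, stage_b)):
        vals = table.loc[table[stage_col] == s, parameter].astype(int)
        cont[i, 0] = int((vals == 1).sum())
        cont[i, 1] = int((vals == 0).sum())
    if method == "fisher":
        return float(sps.fisher_exact(cont, alternative="two-sided")[1])
    if method == "chi2":
        return float(sps.chi2_contingency(cont, correction=True)[1])
    raise ValueError(f"unknown method {method!r}")
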