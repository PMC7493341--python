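"""RT-qPCR relative quantification (delta-delta-Ct) and decision tests.

A Ct value is the PCR cycle at which fluorescence crosses threshold; one
cycle corresponds to a doubling at 100% amplification efficiency.
Relative quantification proceeds per biological replicate: technical
replicates are averaged first, then

    dCt  = Ct_target - Ct_reference        (per condition)
    ddCt = dCt_stress - dCt_control
    RQ   = 2^(-ddCt)

Amplification efficiency comes from a dilution series: the slope of Ct
vs log10(input) gives E = 10^(-1/slope) - 1, with E = 1 (100%) at slope
-1/log10(2) ~ -3.3219.  Regulation calls use one-sample one-tailed
t-tests on RQ values against asymmetric thresholds (mean > 2.0 for up,
mean < 1.0 for down); genotypes are compared with a Welch two-sample
two-tailed t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyResult",
    "amplification_efficiency",
    "ddct",
    "test_regulation",
    "compare_genotypes",
    "concordance",
]

PERFECT_SLOPE = -1.0 / np.log10(2.0)  # ~ -3.3219 cycles per 10-fold dilution

CT_COLUMNS = [
    "bio_rep",
    "gene",
    "role",  # target | reference
    "condition",  # control | stress
    "timepoint",
    "ct",
]


@dataclass(frozen=True)
class EfficiencyResult:
    """Dilution-curve fit: slope, efficiency E = 10^(-1/slope) - 1, R^2."""

    slope: float
    efficiency: float
    r_squared: float


def amplification_efficiency(
    log10_input: np.ndarray, ct: np.ndarray
) -> EfficiencyResult:
    """Fit Ct vs log10(template input) and derive amplification efficiency.

    Requires >= 3 dilution points and a negative slope (more template ->
    earlier threshold crossing); E = 1.0 means perfect doubling.
    """
    log10_input = np.asarray(log10_input, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if len(log10_input) < 3:
        raise ValueError("need at least 3 dilution points")
    fit = stats.linregress(log10_input, ct)
    if fit.slope >= 0:
        raise ValueError(
            f"dilution-curve slope must be negative, got {fit.slope:.3f}"
        )
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyResult(
        slope=float(fit.slope),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
    )


def _mean_ct(table: pd.DataFrame, **criteria) -> pd.Series:
    """Mean Ct over technical replicates per biological replicate."""
    sel = table
    for col, val in criteria.items():
        sel = sel[sel[col] == val]
    if sel.empty:
        raise ValueError(f"no Ct rows matching {criteria}")
    reps = sel.groupby("bio_rep")["ct"]
    short = reps.count() < 3
    if short.any():
        warnings.warn(
            f"fewer than 3 technical replicates for bio reps {list(reps.count()[short].index)}",
            stacklevel=3,
        )
    return reps.mean()


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Relative expression per biological replicate by the ddCt method.

    ``table`` rows carry one technical-replicate Ct each with columns
    bio_rep/gene/role/condition/timepoint/ct.  Technical replicates are
    averaged first; the control condition is the calibrator.  Returns a
    DataFrame indexed by biological replicate with dct_control,
    dct_stress, ddct and rq columns.
    """
    if timepoint is not None:
        table = table[table["timepoint"] == timepoint]
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    def dct(condition: str) -> pd.Series:
        tgt = _mean_ct(table, gene=target, condition=condition)
        try:
            ref = _mean_ct(table, gene=reference, condition=condition)
        except ValueError as exc:
            raise ValueError(f"missing reference rows for {condition}") from exc
        joined = pd.concat([tgt, ref], axis=1, keys=["t", "r"]).dropna()
        if joined.empty:
            raise ValueError(f"no paired target/reference replicates in {condition}")
        return joined["t"] - joined["r"]

    dct_control = dct("control")
    dct_stress = dct("stress")
    pairs = pd.concat([dct_control, dct_stress], axis=1, keys=["control", "stress"]).dropna()
    if pairs.empty:
        raise ValueError("no biological replicate present in both conditions")
    ddct_vals = pairs["stress"] - pairs["control"]
    out = pd.DataFrame(
        {
            "dct_control": pairs["control"],
            "dct_stress": pairs["stress"],
            "ddct": ddct_vals,
            "rq": 2.0 ** (-ddct_vals),
        }
    )
    out.index.name = "bio_rep"
    return out


def test_regulation(
    rq: np.ndarray, alpha: float = 0.05, up_threshold: float = 2.0, down_threshold: float = 1.0
) -> tuple[str, float]:
    """Regulation call from RQ values of one genotype/timepoint.

    'up' iff a one-sided t-test rejects mean <= ``up_threshold``; 'down'
    iff it rejects mean >= ``down_threshold``; otherwise 'ns'.  The
    alternatives are disjoint (thresholds 2.0 and 1.0), so both cannot
    reject.  Zero-variance samples return 'ns' with a warning rather than
    a degenerate t statistic.  Returns (call, p of the attempted test).
    """
    rq = np.asarray(rq, dtype=float)
    if len(rq) < 2:
        raise ValueError("need at least 2 RQ values")
    if np.ptp(rq) == 0.0:
        warnings.warn("zero-variance RQ sample; returning 'ns'", stacklevel=2)
        return "ns", float("nan")
    t_up = stats.ttest_1samp(rq, up_threshold, alternative="greater")
    if t_up.pvalue < alpha:
        return "up", float(t_up.pvalue)
    t_down = stats.ttest_1samp(rq, down_threshold, alternative="less")
    if t_down.pvalue < alpha:
        return "down", float(t_down.pvalue)
    return "ns", float(min(t_up.pvalue, t_down.pvalue))


def compare_genotypes(
    rq_a: np.ndarray, rq_b: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Welch two-sample two-tailed t-test between two genotypes' RQ values."""
    rq_a = np.asarray(rq_a, dtype=float)
    rq_b = np.asarray(rq_b, dtype=float)
    if len(rq_a) < 2 or len(rq_b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(rq_a) == 0.0 and np.ptp(rq_b) == 0.0:
        if np.allclose(rq_a.mean(), rq_b.mean()):
            return 1.0, False
        warnings.warn("both groups have zero variance; comparing means only", stacklevel=2)
        return 0.0, True
    res = stats.ttest_ind(rq_a, rq_b, equal_var=False)
    return float(res.pvalue), bool(res.pvalue < alpha)


def concordance(
    rq_log2: pd.Series, transcriptome_log2: pd.Series
) -> dict[str, float]:
    """Descriptive agreement between qPCR and transcriptome fold changes.

    Both inputs are log2-scale values keyed by (gene, timepoint) or any
    shared index.  Reports the fraction of shared keys with matching
    sign and the Spearman rank correlation.
    """
    joined = pd.concat([rq_log2, transcriptome_log2], axis=1, keys=["rq", "tx"]).dropna()
    if joined.empty:
        raise ValueError("no shared keys between the two result sets")
    sign_agree = float(
        (np.sign(joined["rq"]) == np.sign(joined["tx"])).mean()
    )
    if len(joined) > 2:
        rho = float(stats.spearmanr(joined["rq"], joined["tx"]).statistic)
    else:
        rho = float("nan")
    return {"n": float(len(joined)), "sign_agreement": sign_agree, "spearman_rho": rho}
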