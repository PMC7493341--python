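"""Model-profile clustering of short expression time courses.

Candidate "model profiles" are integer-valued trajectories starting at 0
whose per-step change is bounded by ``c`` — with T timepoints there are
(2c+1)^(T-1) of them.  Each gene's relative-expression trajectory is
assigned to the profile with maximal Pearson correlation; significance of
a profile's gene count is assessed by permuting every gene's timepoint
values independently and re-assigning.  LOESS trend curves summarize the
expression tendency of gene clusters, and a turning-point scan on
smoothed physiological curves (sign changes of the first difference)
locates the sampling times of maximal response variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "enumerate_profiles",
    "assign_genes",
    "ProfileAssignment",
    "ProfileSignificance",
    "profile_significance",
    "loess_trend",
    "turning_points",
]


def enumerate_profiles(n_timepoints: int, c: int = 1) -> np.ndarray:
    """All integer profiles over T timepoints, level_0 = 0, |step| <= c.

    Returns an array of shape ((2c+1)^(T-1), T) in lexicographic step
    order; rows are unique by construction.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if c < 1:
        raise ValueError("step bound c must be >= 1")
    steps = range(-c, c + 1)
    rows = []
    for combo in itertools.product(steps, repeat=n_timepoints - 1):
        rows.append(np.concatenate([[0], np.cumsum(combo)]))
    return np.array(rows, dtype=int)


@dataclass
class ProfileAssignment:
    """Per-gene best profile index and its Pearson correlation.

    ``table`` is indexed by gene id with columns profile / correlation;
    genes with zero variance across timepoints are listed in
    ``unassigned``.
    """

    table: pd.DataFrame
    unassigned: list[str]
    profiles: np.ndarray


def _correlation_matrix(expr: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson correlations (genes x profiles); zero-variance rows give 0."""
    def standardize(a: np.ndarray) -> np.ndarray:
        centered = a - a.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / sd, 0.0)
        return z

    zg = standardize(expr.astype(float))
    zp = standardize(profiles.astype(float))
    return zg @ zp.T / expr.shape[1]


def assign_genes(expr: pd.DataFrame, profiles: np.ndarray) -> ProfileAssignment:
    """Assign each gene trajectory to its max-correlation model profile.

    Ties break to the lowest profile index; zero-variance genes are
    unassigned.  A flat (zero-variance) profile correlates 0 with
    everything and so never wins except by the tie rule at r = 0.
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[1] != profiles.shape[1]:
        raise ValueError("expression table and profiles have different timepoints")
    gene_sd = values.std(axis=1)
    corr = _correlation_matrix(values, profiles)
    best = corr.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    best_r = corr[np.arange(len(best)), best]
    assigned_mask = gene_sd > 0
    table = pd.DataFrame(
        {"profile": best[assigned_mask], "correlation": best_r[assigned_mask]},
        index=expr.index[assigned_mask],
    )
    unassigned = list(expr.index[~assigned_mask])
    return ProfileAssignment(table=table, unassigned=unassigned, profiles=profiles)


@dataclass
class ProfileSignificance:
    """Observed vs permutation-expected gene counts per profile."""

    table: pd.DataFrame  # index profile, columns observed / expected / p


def profile_significance(
    assignment: ProfileAssignment,
    expr: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> ProfileSignificance:
    """Permutation test of profile gene counts.

    Each permutation shuffles every gene's timepoint values independently
    and re-assigns all genes; a profile's p-value is the smoothed fraction
    of permutations whose count reaches the observed count:
    p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    profiles = assignment.profiles
    n_profiles = len(profiles)
    observed = np.zeros(n_profiles, dtype=int)
    counts = assignment.table["profile"].value_counts()
    observed[counts.index.to_numpy()] = counts.to_numpy()
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float)
    exceed = np.zeros(n_profiles, dtype=int)
    expected = np.zeros(n_profiles, dtype=float)
    for _ in range(n_perm):
        permuted = rng.permuted(values, axis=1)
        sd = permuted.std(axis=1)
        corr = _correlation_matrix(permuted, profiles)
        best = corr.argmax(axis=1)
        best = best[sd > 0]
        cnt = np.bincount(best, minlength=n_profiles)
        exceed += cnt >= observed
        expected += cnt
    table = pd.DataFrame(
        {
            "observed": observed,
            "expected": expected / n_perm,
            "p": (1.0 + exceed) / (n_perm + 1.0),
        }
    )
    table.index.name = "profile"
    return ProfileSignificance(table=table)


def loess_trend(t: np.ndarray, y: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Tricube-weighted local linear (LOESS) fit evaluated at the input times.

    Degree-1 exactness: straight-line input is reproduced exactly.  With
    span -> 1 and all points weighted, the fit approaches ordinary least
    squares over the global window.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    smoothed = lowess(y, t, frac=span, it=0, return_sorted=False)
    return np.asarray(smoothed, dtype=float)


def turning_points(series: np.ndarray) -> list[int]:
    """Indices where the slope of a smoothed series changes sign.

    Plateaus (zero first difference) inherit the preceding slope sign, so
    a plateau inside a monotone stretch is not a turning point while a
    plateau at a peak is reported once, at its first index.  Endpoints are
    never reported.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("need at least 3 points")
    diffs = np.diff(series)
    signs = np.sign(diffs)
    # propagate the previous non-zero sign through plateaus
    last = 0.0
    filled = np.empty_like(signs)
    for i, s in enumerate(signs):
        if s != 0:
            last = s
        filled[i] = last
    points = []
    prev = filled[0]
    for i in range(1, len(filled)):
        if filled[i] != 0 and prev != 0 and filled[i] != prev:
            points.append(i)
        if filled[i] != 0:
            prev = filled[i]
    return points
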