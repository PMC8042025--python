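"""Local-ancestry dosage summaries around the focal variant.

Local ancestry assigns every position of an admixed genome an estimated
number of haplotypes (a "dosage" between 0 and 2) derived from each of K
reference populations (here AFR, EAS, EUR; the three dosages sum to 2).
This module averages those dosages in a window around the focal variant
(1 kb up- and downstream by default), contrasts two populations through the
normed difference (a - b) / (a + b), and compares groups of subjects with a
label-shuffling permutation test that preserves group sizes.  A Kendall
tau-b helper supports checking that local ancestry near the variant is not
merely a reflection of global ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortValidationError, POPULATIONS

DOSAGE_COLUMNS = {"AFR": "dos_afr", "EAS": "dos_eas", "EUR": "dos_eur"}
DEFAULT_HALFWIDTH = 1000.0  # bp
DEFAULT_N_PERM = 10_000


class EmptyWindowError(CohortValidationError):
    """No local-ancestry marker falls inside the requested window."""


def window_means(
    local_ancestry: pd.DataFrame,
    center_pos: float,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> pd.DataFrame:
    """Per-subject mean dosages over markers within ``center_pos +- halfwidth``.

    The window is closed on both ends and the mean is the unweighted
    arithmetic mean over in-window markers.  Returns a frame indexed by
    subject_id with the three dosage means and ``n_markers_in_window``.
    """
    lo, hi = center_pos - halfwidth, center_pos + halfwidth
    in_window = local_ancestry[(local_ancestry["pos"] >= lo) & (local_ancestry["pos"] <= hi)]
    if in_window.empty:
        raise EmptyWindowError(
            f"no local-ancestry markers in window [{lo:.0f}, {hi:.0f}] bp"
        )
    grouped = in_window.groupby("subject_id")
    out = grouped[list(DOSAGE_COLUMNS.values())].mean()
    out["n_markers_in_window"] = grouped.size()
    return out


def window_mean(
    local_ancestry: pd.DataFrame,
    subject_id: str,
    center_pos: float,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> pd.Series:
    """Windowed dosage means for a single subject (see :func:`window_means`)."""
    sub = local_ancestry[local_ancestry["subject_id"] == subject_id]
    if sub.empty:
        raise CohortValidationError(f"no local-ancestry rows for subject {subject_id}")
    return window_means(sub, center_pos, halfwidth).loc[subject_id]


def normed_difference(a, b):
    """Signed, scale-free contrast of two dosages: (a - b) / (a + b).

    Lies in [-1, 1]; antisymmetric in its arguments.  When both dosages are
    zero the contrast is undefined and returned as NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise CohortValidationError("dosages must be nonnegative")
    total = a + b
    undefined = total == 0
    if np.any(undefined):
        warnings.warn(
            "normed difference undefined where both dosages are 0; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        result = np.where(undefined, np.nan, (a - b) / np.where(undefined, 1.0, total))
    return float(result) if result.ndim == 0 else result


def subject_normed_differences(
    windows: pd.DataFrame, populations: Sequence[str] = POPULATIONS
) -> pd.DataFrame:
    """Per-subject normed differences for every ordered population pair."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for a, b in combinations(populations, 2):
            out[f"{a}-{b}"] = normed_difference(
                windows[DOSAGE_COLUMNS[a]].to_numpy(),
                windows[DOSAGE_COLUMNS[b]].to_numpy(),
            )
    return pd.DataFrame(out, index=windows.index)


def group_summary(
    windows: pd.DataFrame,
    labels: pd.Series,
    populations: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Group means of dosages and of per-subject normed differences.

    ``labels`` must define exactly two groups over the subjects of
    ``windows``.  One row per population (mean dosage) and per population
    pair (mean per-subject normed difference), with both group means and
    their difference (first group minus second, groups ordered by label).
    """
    labels = labels.reindex(windows.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise CohortValidationError(f"group_summary needs exactly 2 groups, got {groups}")
    masks = {g: (labels == g).to_numpy() for g in groups}
    if any(m.sum() == 0 for m in masks.values()):
        raise CohortValidationError("empty group in group_summary")
    values = {pop: windows[col].to_numpy() for pop, col in DOSAGE_COLUMNS.items()}
    pair_diffs = subject_normed_differences(windows, populations)
    values.update({name: pair_diffs[name].to_numpy() for name in pair_diffs.columns})
    rows = []
    for name, vals in values.items():
        means = {g: float(np.nanmean(vals[masks[g]])) for g in groups}
        rows.append(
            {
                "statistic": name,
                f"mean_{groups[0]}": means[groups[0]],
                f"mean_{groups[1]}": means[groups[1]],
                "difference": means[groups[0]] - means[groups[1]],
            }
        )
    return pd.DataFrame(rows).set_index("statistic")


@dataclass
class PermutationResult:
    """Two-group difference-of-means permutation test result.

    ``p_point`` is the add-one estimator (n_exceed + 1) / (n_perm + 1);
    ``p_report`` mirrors the conventional "<1/n_perm" display when no
    permutation reaches the observed statistic.
    """

    statistic_name: str
    observed: float
    n_perm: int
    n_exceed: int
    p_point: float
    p_report: str
    seed: Optional[int]


def permutation_test(
    values: np.ndarray,
    labels: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    *,
    statistic_name: str = "mean_difference",
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Two-sided permutation test for a difference of group means.

    The null distribution is generated by relabeling subjects without
    replacement, preserving the two group sizes; exceedance is
    ``|perm statistic| >= |observed|``.  Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(labels))
    if values.ndim != 1 or len(labels) != values.size:
        raise CohortValidationError("values and labels must be aligned 1-d sequences")
    if not np.all(np.isfinite(values)):
        raise CohortValidationError("permutation test requires finite values")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise CohortValidationError(f"permutation test needs exactly 2 groups, got {groups}")
    mask = (labels == groups[0]).to_numpy()
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise CohortValidationError("both groups must be non-empty")
    total = values.sum()
    observed = values[mask].mean() - values[~mask].mean()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = values.size
    n_exceed = 0
    chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # first n1 entries of each random permutation form the shuffled group 1
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :n1]
        sums = values[idx].sum(axis=1)
        stat = sums / n1 - (total - sums) / n2
        n_exceed += int(np.sum(np.abs(stat) >= abs(observed) - 1e-12))
        done += m
    p_point = (n_exceed + 1) / (n_perm + 1)
    p_report = f"<{1.0 / n_perm:.2E}" if n_exceed == 0 else f"{p_point:.2E}"
    return PermutationResult(
        statistic_name=statistic_name,
        observed=float(observed),
        n_perm=n_perm,
        n_exceed=n_exceed,
        p_point=float(p_point),
        p_report=p_report,
        seed=seed,
    )


def compare_groups(
    windows: pd.DataFrame,
    labels: pd.Series,
    *,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    populations: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Group summary plus permutation p-values, one row per statistic.

    This mirrors the layout of a dosage-comparison table: single-population
    mean dosages and pairwise mean normed differences per group, their
    difference, and the permutation p-value of that difference.  Subjects
    whose pairwise normed difference is undefined (both dosages zero) are
    excluded from that pair's test.
    """
    labels = labels.reindex(windows.index)
    summary = group_summary(windows, labels, populations)
    groups = sorted(labels.dropna().unique())
    values = {pop: windows[col].to_numpy() for pop, col in DOSAGE_COLUMNS.items()}
    pair_diffs = subject_normed_differences(windows, populations)
    values.update({name: pair_diffs[name].to_numpy() for name in pair_diffs.columns})
    rows = []
    ss = np.random.SeedSequence(seed)
    stat_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(values))]
    for stat_seed, (name, vals) in zip(stat_seeds, values.items()):
        keep = np.isfinite(vals) & labels.notna().to_numpy()
        result = permutation_test(
            vals[keep],
            labels.to_numpy()[keep],
            n_perm=n_perm,
            seed=stat_seed,
            statistic_name=name,
        )
        rows.append(
            {
                "statistic": name,
                "group_a": groups[0],
                "group_b": groups[1],
                "mean_a": summary.loc[name, f"mean_{groups[0]}"],
                "mean_b": summary.loc[name, f"mean_{groups[1]}"],
                "difference": summary.loc[name, "difference"],
                "n_used": int(keep.sum()),
                "p_point": result.p_point,
                "p_report": result.p_report,
            }
        )
    return pd.DataFrame(rows).set_index("statistic")


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b with tie correction and normal-approximation p-value.

    Returns ``(nan, nan)`` with a warning when either variable is constant
    (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise CohortValidationError("kendall_tau_b needs paired 1-d data with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CohortValidationError("kendall_tau_b requires finite values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("tau-b undefined for constant input; returning NaN", RuntimeWarning)
        return float("nan"), float("nan")
    tau, p = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(tau), float(p)
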