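"""Sleep variables, Markov transition matrices, and group comparisons.

Sleep variables follow the usual polysomnography conventions: total sleep
time (TST) counts non-wake epochs; sleep onset latency (SOL) is the time to
the first epoch of any sleep stage; wake after sleep onset (WASO) counts
wake epochs between sleep onset and the final sleep epoch; stage
percentages are relative to TST; bouts are maximal same-stage runs.

Transition probabilities are first-order Markov estimates: per participant,
each night is truncated to a fixed chain length (960 epochs of 30 s = 8 h),
transitions are counted within nights (never across the night boundary),
pooled, and row-normalized.

Group comparisons mirror a common nonparametric workflow: one-way ANOVA
with eta-squared across the three ISI groups; if p < 0.05, pairwise
Wilcoxon rank-sum (Mann-Whitney U) tests with small-sample-corrected
Hedges' g.  A chi-squared test of independence is provided for categorical
tables.  No multiple-comparison correction is applied; pairwise p-values
are reported raw.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recording import STAGES, canonical_stage

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


# ----------------------------------------------------------------------
# sleep variables
# ----------------------------------------------------------------------
@dataclass
class SleepVariables:
    """Summary variables of one hypnogram, in minutes / percent of TST."""

    tst_min: float
    sol_min: float | None  # None when no sleep occurs
    waso_min: float
    stage_pct: dict[str, float]  # over R, N1, N2, N3; sums to 100 if TST > 0
    bout_mean_min: dict[str, float]  # mean same-stage run length per stage

    def to_dict(self) -> dict:
        out = {"TST_min": self.tst_min, "SOL_min": self.sol_min,
               "WASO_min": self.waso_min}
        for s, v in self.stage_pct.items():
            out[f"{s}_pct"] = v
        for s, v in self.bout_mean_min.items():
            out[f"{s}_bout_min"] = v
        return out


def _runs(seq: list[str]) -> list[tuple[str, int]]:
    return [(s, len(list(g))) for s, g in itertools.groupby(seq)]


def sleep_variables(hypnogram: list[str], epoch_s: float = 30.0
                    ) -> SleepVariables:
    """Compute TST / SOL / WASO / stage % / bout lengths from a hypnogram."""
    if not hypnogram:
        raise ValueError("hypnogram is empty")
    hyp = [canonical_stage(s) for s in hypnogram]
    minutes = epoch_s / 60.0
    is_sleep = np.array([s != "W" for s in hyp])
    tst = float(is_sleep.sum() * minutes)
    if not is_sleep.any():
        warnings.warn("all-wake hypnogram: SOL undefined, TST = 0")
        return SleepVariables(0.0, None, 0.0,
                              {s: 0.0 for s in ("R", "N1", "N2", "N3")}, {})
    first = int(np.argmax(is_sleep))
    last = int(len(hyp) - 1 - np.argmax(is_sleep[::-1]))
    sol = first * minutes
    waso = float(sum(1 for s in hyp[first:last + 1] if s == "W") * minutes)
    counts = {s: hyp.count(s) for s in STAGES}
    stage_pct = {
        s: 100.0 * counts[s] * minutes / tst for s in ("R", "N1", "N2", "N3")
    }
    bouts: dict[str, list[int]] = {}
    for stage, length in _runs(hyp):
        bouts.setdefault(stage, []).append(length)
    bout_mean = {
        s: float(np.mean(v) * minutes) for s, v in bouts.items() if s != "W"
    }
    return SleepVariables(tst, sol, waso, stage_pct, bout_mean)


# ----------------------------------------------------------------------
# transitions
# ----------------------------------------------------------------------
@dataclass
class TransitionMatrix:
    """Row-stochastic 5x5 stage-transition estimate with row counts.

    Rows with zero observations are undefined and reported as NaN.
    """

    probs: np.ndarray  # (5, 5); NaN rows where count == 0
    counts: np.ndarray  # (5,) observations per source stage
    stages: tuple[str, ...] = STAGES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.stages,
                            columns=self.stages)


def estimate_transitions(hypnograms: list[list[str]],
                         chain_length: int = 960) -> TransitionMatrix:
    """Pooled within-night transition counts for one participant.

    Each night is truncated at ``chain_length`` epochs (shorter nights are
    used in full; nothing is padded) and the night boundary contributes no
    transition.
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    counts = np.zeros((5, 5), dtype=float)
    for hyp in hypnograms:
        idx = [_STAGE_INDEX[canonical_stage(s)] for s in hyp[:chain_length]]
        for a, b in zip(idx[:-1], idx[1:]):
            counts[a, b] += 1
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row[:, None]
    probs[row == 0] = np.nan
    return TransitionMatrix(probs, row)


def group_transition_summary(
    matrices: dict[str, list[TransitionMatrix]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per group: (mean, SD) of transition percentages across participants.

    NaN (undefined) rows are ignored entrywise, matching a summary over the
    participants that actually visited a stage.
    """
    out = {}
    for group, mats in matrices.items():
        stack = np.stack([m.probs for m in mats]) * 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[group] = (np.nanmean(stack, axis=0), np.nanstd(stack, axis=0))
    return out


# ----------------------------------------------------------------------
# group statistics
# ----------------------------------------------------------------------
@dataclass
class GroupTestResult:
    """One omnibus or pairwise comparison."""

    test: str  # "anova", "ranksum", or "chi2"
    statistic: float
    p_value: float
    effect_size: float | None
    effect_name: str | None
    groups: tuple[str, ...]
    n: tuple[int, ...]


@dataclass
class GroupComparison:
    """ANOVA omnibus plus (when p < alpha) pairwise rank-sum follow-ups."""

    omnibus: GroupTestResult
    pairwise: list[GroupTestResult] = field(default_factory=list)


def eta_squared(groups: list[np.ndarray]) -> float:
    """Between-group sum of squares over total sum of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_total = float(((allv - grand) ** 2).sum())
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the small-sample bias correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * d)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum via the Mann-Whitney U statistic.

    Exact enumeration for small samples without ties, tie-corrected normal
    approximation otherwise.
    """
    method = "exact" if (len(a) <= 20 and len(b) <= 20) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # ties with exact method
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(values: dict[str, np.ndarray], alpha: float = 0.05
                   ) -> GroupComparison:
    """One-way ANOVA with eta-squared; pairwise follow-ups when p < alpha."""
    names = tuple(values)
    arrays = [np.asarray(values[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name} has fewer than 2 observations")
    f_stat, p = stats.f_oneway(*arrays)
    omnibus = GroupTestResult(
        "anova", float(f_stat), float(p), eta_squared(arrays), "eta2",
        names, tuple(len(a) for a in arrays),
    )
    pairwise = []
    if p < alpha:
        for (na, a), (nb, b) in itertools.combinations(zip(names, arrays), 2):
            u, pu = rank_sum_test(a, b)
            pairwise.append(
                GroupTestResult("ranksum", u, pu, hedges_g(a, b), "hedges_g",
                                (na, nb), (len(a), len(b)))
            )
    return GroupComparison(omnibus, pairwise)


def chi2_independence(table: np.ndarray) -> GroupTestResult:
    """Chi-squared test of independence on a contingency table."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult(
        "chi2", float(chi2), float(p), None, None,
        tuple(f"col{i}" for i in range(table.shape[1])),
        tuple(int(n) for n in table.sum(axis=1)),
    )
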