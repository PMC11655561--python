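"""Behavioral statistics for auditory fear-conditioning experiments.

The behavioral readout is the percentage of time an animal freezes to the
conditioned tone, measured at three phases: immediately after training
(``training-post``), at memory reactivation 24 h later (``reactivation``) and
at test a further 24 h later (``test``). This module provides

* the conditioned-freezing inclusion rule (animals must freeze strictly more
  than 37% at reactivation to count as having acquired the memory),
* a two-way mixed (repeated-measures) ANOVA with drug group as the
  between-subject factor and phase/day as the within-subject factor,
* Tukey HSD post-hoc comparisons driven by an externally supplied error term,
* one-way ANOVA entry point for single-endpoint assays (Barnes maze, open
  field), and
* an a priori power / sample-size computation for the repeated-measures
  design based on the noncentral F distribution.

Power convention
----------------
``rm_anova_power`` follows the G*Power "ANOVA: repeated measures, between
factors" formulation: with Cohen's f on the group means, total N, m repeated
measures, correlation rho among them and nonsphericity epsilon,

    lambda = f^2 * N * m * eps / (1 + (m - 1) * rho),
    df1 = k - 1,  df2 = N - k,

and power = P(F'(df1, df2, lambda) > F_crit(1 - alpha)). With f = 0.58,
alpha = 0.05, power 0.8, k = 6 groups, m = 3 measures, rho = 0.5 this yields
a required total N of 36 (n = 6 per group). This is the only standard
repeated-measures formulation that returns 36 from those inputs; see
docs/methods.md for the discussion of alternatives.

Degenerate-data conventions (shared with :mod:`engramap.binstats`): an effect
with zero sum of squares against a zero error term reports F = 0, p = 1; a
nonzero effect against a zero error term reports p = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import binstats

__all__ = [
    "PHASES",
    "FreezingRecord",
    "ExclusionResult",
    "EffectResult",
    "RmAnovaResult",
    "PowerSpec",
    "records_to_frame",
    "exclusion_filter",
    "rm_anova",
    "tukey_hsd",
    "tukey_posthoc_groups",
    "rm_anova_power",
    "rm_anova_sample_size",
    "endpoint_anova",
]

#: Canonical phase labels, in chronological order.
PHASES: tuple[str, str, str] = ("training-post", "reactivation", "test")

#: Conditioned-freezing inclusion threshold (percent at reactivation, strict).
DEFAULT_FREEZING_THRESHOLD = 37.0


@dataclass(frozen=True)
class FreezingRecord:
    """One animal's freezing percentage in one phase."""

    animal_id: str
    group: str
    phase: str
    percent_freezing: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_freezing <= 100.0:
            raise ValueError(
                f"percent_freezing {self.percent_freezing} outside [0, 100] "
                f"for animal {self.animal_id!r}"
            )


@dataclass(frozen=True)
class ExclusionResult:
    retained: list[str]
    excluded: list[str]
    threshold: float

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect line: sums of squares, dfs, F and p."""

    ss: float
    df1: int
    df2: int
    ms: float
    F: float
    p: float


@dataclass(frozen=True)
class RmAnovaResult:
    """Two-way mixed ANOVA output.

    ``effects`` holds 'group' (between-subject), 'phase' (within-subject) and
    'interaction'; ``ss_table`` is the full sums-of-squares decomposition.
    """

    effects: Mapping[str, EffectResult]
    ss_table: pd.DataFrame
    n_subjects: int
    n_groups: int
    n_phases: int
    ms_between_error: float
    df_between_error: int


def records_to_frame(records: Iterable[FreezingRecord]) -> pd.DataFrame:
    """Long-format DataFrame with columns animal_id, group, phase, percent_freezing."""
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "phase": r.phase,
                "percent_freezing": r.percent_freezing,
            }
            for r in records
        ]
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        need = {"animal_id", "group", "phase", "percent_freezing"}
        missing = need - set(records.columns)
        if missing:
            raise ValueError(f"freezing table missing columns: {sorted(missing)}")
        return records
    return records_to_frame(records)


def exclusion_filter(
    records, threshold: float = DEFAULT_FREEZING_THRESHOLD
) -> ExclusionResult:
    """Apply the conditioned-freezing inclusion rule.

    An animal is retained iff its reactivation freezing is strictly greater
    than ``threshold`` percent (an animal at exactly the threshold is
    excluded). Animals lacking a reactivation record raise an error naming
    them.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    df = _as_frame(records)
    if df.empty:
        return ExclusionResult(retained=[], excluded=[], threshold=threshold)
    react = df[df["phase"] == "reactivation"].set_index("animal_id")["percent_freezing"]
    all_animals = pd.unique(df["animal_id"])
    missing = [a for a in all_animals if a not in react.index]
    if missing:
        raise ValueError(f"animal(s) missing a reactivation record: {missing}")
    retained = [a for a in all_animals if react[a] > threshold]
    excluded = [a for a in all_animals if react[a] <= threshold]
    return ExclusionResult(retained=retained, excluded=excluded, threshold=threshold)


def _f_p(ss_effect: float, df1: int, ss_error: float, df2: int) -> tuple[float, float, float]:
    """(MS, F, p) with the shared degenerate conventions."""
    ms_e = ss_error / df2 if df2 > 0 else 0.0
    ms = ss_effect / df1
    if ms_e <= 0.0:
        if ss_effect <= 0.0:
            return ms, 0.0, 1.0
        return ms, np.inf, 0.0
    F = ms / ms_e
    return ms, float(F), float(stats.f.sf(F, df1, df2))


def rm_anova(records) -> RmAnovaResult:
    """Two-way mixed ANOVA: group (between-subject) x phase (within-subject).

    Requires a balanced within-subject layout (every animal observed in every
    phase); group sizes may differ. The group effect is tested against the
    between-subject error (df = N - k); phase and the group x phase
    interaction against the within-subject error (df = (N - k)(m - 1)).

    Raises
    ------
    ValueError
        If fewer than 2 groups or phases, or if any animal misses a phase
        (offending animals are listed).
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no freezing records")
    if df.duplicated(["animal_id", "phase"]).any():
        dup = df[df.duplicated(["animal_id", "phase"])]["animal_id"].unique().tolist()
        raise ValueError(f"duplicate phase records for animal(s): {dup}")
    wide = df.pivot(index="animal_id", columns="phase", values="percent_freezing")
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"unbalanced phases; animal(s) missing observations: {bad}")
    groups = df.drop_duplicates("animal_id").set_index("animal_id")["group"]
    k = groups.nunique()
    m = wide.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups")
    if m < 2:
        raise ValueError("need >= 2 phases")
    n_subj = wide.shape[0]

    y = wide.to_numpy(dtype=float)  # subjects x phases
    g = groups.loc[wide.index].to_numpy()
    grand = y.mean()
    subj_means = y.mean(axis=1)
    phase_means = y.mean(axis=0)

    labels = pd.unique(g)
    n_g = np.array([(g == lab).sum() for lab in labels])
    group_means = np.array([y[g == lab].mean() for lab in labels])
    cell_means = np.array([y[g == lab].mean(axis=0) for lab in labels])  # k x m

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())
    ss_group = float(m * (n_g * (group_means - grand) ** 2).sum())
    ss_subj_error = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_phase = float(n_subj * ((phase_means - grand) ** 2).sum())
    inter_dev = cell_means - group_means[:, None] - phase_means[None, :] + grand
    ss_inter = float((n_g[:, None] * inter_dev**2).sum())
    ss_within_error = ss_within - ss_phase - ss_inter
    # clip tiny negatives from float cancellation
    ss_subj_error = max(ss_subj_error, 0.0)
    ss_within_error = max(ss_within_error, 0.0)

    df_group, df_bse = k - 1, n_subj - k
    df_phase, df_inter = m - 1, (k - 1) * (m - 1)
    df_wse = (n_subj - k) * (m - 1)

    ms_g, F_g, p_g = _f_p(ss_group, df_group, ss_subj_error, df_bse)
    ms_p, F_p, p_p = _f_p(ss_phase, df_phase, ss_within_error, df_wse)
    ms_i, F_i, p_i = _f_p(ss_inter, df_inter, ss_within_error, df_wse)

    effects = {
        "group": EffectResult(ss_group, df_group, df_bse, ms_g, F_g, p_g),
        "phase": EffectResult(ss_phase, df_phase, df_wse, ms_p, F_p, p_p),
        "interaction": EffectResult(ss_inter, df_inter, df_wse, ms_i, F_i, p_i),
    }
    table = pd.DataFrame(
        {
            "source": [
                "group",
                "subjects-within-groups",
                "phase",
                "group:phase",
                "phase-by-subjects-within-groups",
                "total",
            ],
            "ss": [ss_group, ss_subj_error, ss_phase, ss_inter, ss_within_error, ss_total],
            "df": [df_group, df_bse, df_phase, df_inter, df_wse, n_subj * m - 1],
        }
    )
    return RmAnovaResult(
        effects=effects,
        ss_table=table,
        n_subjects=n_subj,
        n_groups=k,
        n_phases=m,
        ms_between_error=ss_subj_error / df_bse if df_bse > 0 else 0.0,
        df_between_error=df_bse,
    )


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    error_mean_square: float,
    error_df: int,
) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons with a supplied error term.

    For each pair, q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) and
    the adjusted p is the studentized-range tail P(Q_{k, df} > q). Passing the
    between-subject mean square from :func:`rm_anova` (on the subject-mean
    scale) gives the post-hoc group comparisons of the mixed design.

    A zero error mean square yields adjusted p = 0 for unequal means and 1
    for equal means, mirroring the degenerate ANOVA conventions.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if error_df < 1:
        raise ValueError("error_df must be >= 1")
    if error_mean_square < 0:
        raise ValueError("error_mean_square must be >= 0")
    k = len(groups)
    rows = []
    for (la, xa), (lb, xb) in itertools.combinations(groups.items(), 2):
        xa = np.asarray(xa, float)
        xb = np.asarray(xb, float)
        diff = xa.mean() - xb.mean()
        if error_mean_square == 0.0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(error_mean_square / 2.0 * (1.0 / len(xa) + 1.0 / len(xb)))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, error_df))
        rows.append(
            {
                "group_1": la,
                "group_2": lb,
                "mean_diff": diff,
                "q_stat": q,
                "p_adj": min(max(p, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


def tukey_posthoc_groups(records) -> pd.DataFrame:
    """Tukey HSD on per-animal phase means, using the between-subject error.

    Convenience wrapper: averages each animal over phases, pools the
    within-group variance of those subject means (this equals the mixed
    ANOVA's between-subject mean square divided by the number of phases) and
    runs :func:`tukey_hsd`.
    """
    df = _as_frame(records)
    subj = df.groupby(["animal_id", "group"], sort=False)["percent_freezing"].mean().reset_index()
    groups = {
        lab: sub["percent_freezing"].to_numpy()
        for lab, sub in subj.groupby("group", sort=False)
    }
    n_total = len(subj)
    k = len(groups)
    if k < 2 or n_total - k < 1:
        raise ValueError("need >= 2 groups and at least one error df")
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / (n_total - k)
    return tukey_hsd(groups, error_mean_square=mse, error_df=n_total - k)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the a priori repeated-measures power analysis.

    f is Cohen's effect size for the group means (between-group SD of means /
    within-group SD); rho is the assumed correlation among the repeated
    measures; epsilon the nonsphericity correction (1 = sphericity).
    """

    f: float
    alpha: float = 0.05
    power: float = 0.8
    k: int = 6
    m: int = 3
    rho: float = 0.5
    eps: float = 1.0

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError("effect size f must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("target power must be in (0, 1)")
        if self.k < 2:
            raise ValueError("need k >= 2 groups")
        if self.m < 2:
            raise ValueError("need m >= 2 repeated measures")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.eps <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def rm_anova_power(spec: PowerSpec, N: int) -> float:
    """Achieved power of the between-group test at total sample size N.

    Noncentral-F computation with lambda = f^2 N m eps / (1 + (m-1) rho),
    df1 = k - 1, df2 = N - k (see module docstring for the convention).
    """
    if N < spec.k + 1:
        raise ValueError(f"N must be >= k + 1 = {spec.k + 1}")
    lam = spec.f**2 * N * spec.m * spec.eps / (1.0 + (spec.m - 1) * spec.rho)
    df1 = spec.k - 1
    df2 = N - spec.k
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def rm_anova_sample_size(spec: PowerSpec, group_multiple: int | None = None) -> int:
    """Smallest total N, a multiple of k, reaching the target power.

    Equal group sizes are enforced (N is a multiple of ``group_multiple``,
    which must equal the number of groups k). Raises if the target power is
    unreachable below N = 10^6.
    """
    if group_multiple is None:
        group_multiple = spec.k
    if group_multiple != spec.k:
        raise ValueError("group_multiple must equal the number of groups k")
    N = spec.k  # first candidate below has df2 >= 1
    while True:
        N += spec.k
        if N > 10**6:
            raise ValueError("target power unreachable for N <= 1e6")
        if N - spec.k >= 1 and rm_anova_power(spec, N) >= spec.power:
            return N


def endpoint_anova(samples: Mapping[str, Sequence[float]]):
    """One-way ANOVA for single-endpoint behavioral assays.

    Entry point for Barnes-maze endpoints (primary latency, primary errors,
    time in target quadrant) and open-field line crossings; delegates to
    :func:`engramap.binstats.one_way_anova`.
    """
    return binstats.one_way_anova(list(samples.values()))
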