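"""Mass-univariate per-bin statistics with FDR-controlled hotspot detection.

Each bin of the count matrices is tested with a one-way fixed-effects ANOVA
across experimental conditions (animals as replicates). The per-bin p values
form one multiple-testing family — the bins whose center lies inside the ROI
contour and which are not structurally empty — and are converted to q values
by the Benjamini–Hochberg step-up procedure; bins with q below the tolerable
FDR limit (default 0.1) are the detected hotspots. Inside significant bins,
uncorrected planned pairwise comparisons classify the pattern of the effect
(all treatments below the reference vs a single-treatment-specific change),
reproducing the colored-bin reading of a q-value matrix. The whole-ROI
per-animal total count is compared with the same one-way ANOVA.

Degenerate-data conventions (count data at n ~ 6 hit these routinely):

* all values equal across all groups -> F = 0, p = 1;
* zero within-group variance with unequal means -> p = 0;
* bins whose counts are zero for every animal are structurally empty and are
  excluded from the FDR family (testing them would only inflate the family
  size m).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .topography import BinGrid, CountMatrix

__all__ = [
    "AnovaResult",
    "BinStatResult",
    "TotalCountResult",
    "one_way_anova",
    "bh_fdr",
    "mass_univariate",
    "classify_bins",
    "total_count_anova",
    "CODE_NONE",
    "CODE_ALL_LOWER",
    "CODE_OTHER",
]

CODE_NONE = "none"
CODE_ALL_LOWER = "all-drugs-lower"
CODE_OTHER = "other"


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class BinStatResult:
    """Per-bin F/p/q matrices and hotspot classification.

    Arrays are (rows, cols); entries outside the FDR family are NaN.
    ``family_mask`` marks the bins entering the Benjamini–Hochberg family;
    ``sig_mask`` the bins with q < ``q_threshold``. ``codes`` holds the
    per-bin classification string (:data:`CODE_NONE` until
    :func:`classify_bins` runs).
    """

    F: np.ndarray
    p: np.ndarray
    q: np.ndarray
    family_mask: np.ndarray
    sig_mask: np.ndarray
    codes: np.ndarray
    q_threshold: float
    group_labels: list[str]

    @property
    def n_family(self) -> int:
        return int(self.family_mask.sum())

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


@dataclass(frozen=True)
class TotalCountResult:
    """Whole-ROI per-animal totals and their one-way ANOVA."""

    totals: Mapping[str, np.ndarray]  # group -> per-animal totals
    anova: AnovaResult

    @property
    def group_means(self) -> dict[str, float]:
        return {g: float(np.mean(v)) for g, v in self.totals.items()}


def one_way_anova(samples: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from sums of squares.

    ``samples`` is one sequence of values per group. Degenerate conventions:
    all values equal everywhere -> (F=0, p=1); zero within-group variance with
    unequal means -> (F=inf, p=0).
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs >= 1 value")
    n = np.array([a.size for a in arrays])
    N = int(n.sum())
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1, df2 = k - 1, N - k
    if df2 < 1:
        raise ValueError("no within-group degrees of freedom (every group has 1 value)")
    if ssw <= 0.0:
        if ssb <= 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(np.inf, df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


def bh_fdr(p_values: Sequence[float], q_threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q values and rejection set.

    Sort p ascending; q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped
    back to the input order. The rejection set is {q < q_threshold} (strict,
    matching a "tolerable limit" reading of the threshold).

    Returns (q_values, reject) as arrays aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < q_threshold


def _group_matrices(matrices: Sequence[CountMatrix]) -> dict[str, np.ndarray]:
    """Stack matrices by group label into (n_animals, rows, cols) arrays."""
    shapes = {m.counts.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"mixed grids: count-matrix shapes {sorted(shapes)}")
    groups: dict[str, list[np.ndarray]] = {}
    for m in matrices:
        groups.setdefault(m.group, []).append(m.counts)
    return {g: np.stack(v).astype(float) for g, v in groups.items()}


def _vectorized_anova(stacks: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-bin one-way ANOVA over all bins at once.

    Returns (F, p, df1, df2) with the same degenerate conventions as
    :func:`one_way_anova`; F and p have the bin-matrix shape.
    """
    labels = list(stacks)
    n = np.array([stacks[g].shape[0] for g in labels])
    k = len(labels)
    N = int(n.sum())
    df1, df2 = k - 1, N - k
    means = np.stack([stacks[g].mean(axis=0) for g in labels])  # k x rows x cols
    grand = sum(stacks[g].sum(axis=0) for g in labels) / N
    ssb = (n[:, None, None] * (means - grand) ** 2).sum(axis=0)
    ssw = sum(((stacks[g] - means[i]) ** 2).sum(axis=0) for i, g in enumerate(labels))
    F = np.full(grand.shape, np.nan)
    p = np.full(grand.shape, np.nan)
    zero_w = ssw <= 0.0
    both_zero = zero_w & (ssb <= 0.0)
    eff_only = zero_w & (ssb > 0.0)
    F[both_zero] = 0.0
    p[both_zero] = 1.0
    F[eff_only] = np.inf
    p[eff_only] = 0.0
    ok = ~zero_w
    F[ok] = (ssb[ok] / df1) / (ssw[ok] / df2)
    p[ok] = stats.f.sf(F[ok], df1, df2)
    return F, p, df1, df2


def mass_univariate(
    matrices: Sequence[CountMatrix],
    grid: BinGrid,
    q_threshold: float = 0.1,
) -> BinStatResult:
    """Per-bin one-way ANOVA across conditions with BH-FDR over the bin family.

    The family consists of the bins inside the ROI (grid mask) that are not
    structurally empty (zero for every animal). Bins outside the family carry
    NaN statistics and are never significant.

    Raises
    ------
    ValueError
        On mixed grids or fewer than 2 conditions.
    """
    stacks = _group_matrices(matrices)
    if len(stacks) < 2:
        raise ValueError("need >= 2 conditions")
    shape = next(iter(stacks.values())).shape[1:]
    if shape != (grid.rows, grid.cols):
        raise ValueError(
            f"count matrices of shape {shape} do not match grid {grid.rows}x{grid.cols}"
        )
    all_zero = np.all([np.all(s == 0, axis=0) for s in stacks.values()], axis=0)
    family = grid.mask & ~all_zero
    F, p, _, _ = _vectorized_anova(stacks)
    F = np.where(family, F, np.nan)
    p = np.where(family, p, np.nan)
    q = np.full_like(p, np.nan)
    sig = np.zeros_like(family)
    if family.any():
        qf, rej = bh_fdr(p[family], q_threshold)
        q[family] = qf
        sig[family] = rej
    codes = np.full(family.shape, CODE_NONE, dtype=object)
    return BinStatResult(
        F=F,
        p=p,
        q=q,
        family_mask=family,
        sig_mask=sig,
        codes=codes,
        q_threshold=q_threshold,
        group_labels=list(stacks),
    )


def _pooled_t_p(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    """Two-sided two-sample t-test p with the degenerate zero-variance rule."""
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 <= 0.0:
            return 1.0 if diff == 0 else 0.0
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 <= 0.0:
            return 1.0 if diff == 0 else 0.0
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    return float(2.0 * stats.t.sf(abs(t), df))


def classify_bins(
    result: BinStatResult,
    matrices: Sequence[CountMatrix],
    reference_group: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> np.ndarray:
    """Planned pairwise comparisons inside FDR-significant bins.

    Within each significant bin, every non-reference (treatment) group is
    compared to the reference and treatments are compared among themselves
    with uncorrected two-sided two-sample t-tests at level ``alpha`` (pooled
    variance by default, Welch with ``welch=True``). Codes:

    * ``all-drugs-lower`` — every treatment is significantly below the
      reference and no two treatments differ;
    * ``"<label>-specific"`` — treatment <label> is significantly below both
      the reference and every other treatment;
    * ``other`` — a significant bin matching neither pattern;
    * ``none`` — non-significant bins, whatever their means.

    The codes are written into ``result.codes`` and also returned.
    """
    stacks = _group_matrices(matrices)
    if reference_group not in stacks:
        raise ValueError(f"reference group {reference_group!r} absent from the data")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    treatments = [g for g in stacks if g != reference_group]
    codes = np.full(result.sig_mask.shape, CODE_NONE, dtype=object)
    for r, c in zip(*np.nonzero(result.sig_mask)):
        ref = stacks[reference_group][:, r, c]
        lower_than_ref = {}
        for t in treatments:
            x = stacks[t][:, r, c]
            p = _pooled_t_p(x, ref, welch)
            lower_than_ref[t] = (p < alpha) and (x.mean() < ref.mean())
        pair_sig = {}
        for ta, tb in itertools.combinations(treatments, 2):
            xa, xb = stacks[ta][:, r, c], stacks[tb][:, r, c]
            pair_sig[(ta, tb)] = _pooled_t_p(xa, xb, welch) < alpha
        code = CODE_OTHER
        if treatments and all(lower_than_ref.values()) and not any(pair_sig.values()):
            code = CODE_ALL_LOWER
        else:
            for t in treatments:
                others = [o for o in treatments if o != t]
                below_all_others = all(
                    pair_sig[tuple(sorted((t, o), key=treatments.index))]
                    and stacks[t][:, r, c].mean() < stacks[o][:, r, c].mean()
                    for o in others
                )
                if lower_than_ref[t] and others and below_all_others:
                    code = f"{t}-specific"
                    break
        codes[r, c] = code
    result.codes = codes
    return codes


def total_count_anova(
    matrices: Sequence[CountMatrix], grid: BinGrid | None = None
) -> TotalCountResult:
    """Whole-ROI comparison: per-animal total counts, one-way ANOVA.

    With a grid, totals run over the bins inside the ROI family; without one,
    over all bins (equivalent when every point fell in a family bin).
    """
    stacks = _group_matrices(matrices)
    if len(stacks) < 2:
        raise ValueError("need >= 2 conditions")
    if grid is not None:
        totals = {g: s[:, grid.mask].sum(axis=1) for g, s in stacks.items()}
    else:
        totals = {g: s.sum(axis=(1, 2)) for g, s in stacks.items()}
    return TotalCountResult(
        totals=totals, anova=one_way_anova([totals[g] for g in totals])
    )
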