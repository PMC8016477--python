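"""Group-level inference for peri-event tensors and behavior.

The central procedure is a bin-wise two-group permutation test on z-scored
peri-event traces: trials from both groups are pooled and re-partitioned
(preserving group sizes) 1000 times; the per-bin two-sided p is the add-one
smoothed rank of the observed mean difference in the permutation null.  Raw
p values are Benjamini-Hochberg corrected across the analysis-window bins,
and only runs of at least four consecutive significant bins are reported as
significant epochs — a guard against isolated bins surviving by chance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .perievent import PeriEventTensor


class StatsError(ValueError):
    pass


@dataclass
class PermutationResult:
    bin_times_s: np.ndarray
    observed_diff: np.ndarray       # mean(A) - mean(B) per bin, z units
    p_raw: np.ndarray
    p_adj: np.ndarray
    null_sd: np.ndarray             # SD of the permutation null per bin
    significant_epochs: list = field(default_factory=list)
    n_perm: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    min_run: int = 4


def bh_fdr(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw <= 0) | (p_raw > 1)):
        raise StatsError("p values must lie in (0, 1]")
    return multipletests(p_raw, method="fdr_bh")[1]


def significant_epochs(
    p_adj: np.ndarray,
    bin_times_s: np.ndarray,
    alpha: float = 0.05,
    min_run: int = 4,
    bin_s: float | None = None,
) -> list[tuple[float, float]]:
    """Maximal runs of >= min_run consecutive bins with p_adj < alpha,
    reported as (start_s, end_s) time intervals over full bins."""
    p_adj = np.asarray(p_adj, dtype=float)
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    if bin_s is None:
        bin_s = float(np.median(np.diff(bin_times_s))) if bin_times_s.size > 1 else 0.0
    sig = p_adj < alpha
    epochs = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                epochs.append((float(bin_times_s[i] - bin_s / 2),
                               float(bin_times_s[j] + bin_s / 2)))
            i = j + 1
        else:
            i += 1
    return epochs


def permutation_bin_test(
    group_a: np.ndarray | PeriEventTensor,
    group_b: np.ndarray | PeriEventTensor,
    bin_times_s: np.ndarray | None = None,
    analysis_window: tuple[float, float] = (-2.0, 2.0),
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    min_run: int = 4,
) -> PermutationResult:
    """Bin-wise two-group permutation test over the analysis window.

    The resampling unit is the trial (row); rows are exchanged wholesale
    between groups, never individual bins.  p_raw uses add-one smoothing,
    (1 + #{|null| >= |obs|}) / (n_perm + 1), so no p is exactly zero.  BH-FDR
    is applied across the analysis-window bins only.
    """
    if isinstance(group_a, PeriEventTensor):
        if bin_times_s is None:
            bin_times_s = group_a.bin_centers_s
        analysis_window = group_a.analysis_window_s
        group_a = group_a.z
    if isinstance(group_b, PeriEventTensor):
        group_b = group_b.z
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise StatsError("need at least 2 rows per group")
    if a.shape[1] != b.shape[1]:
        raise StatsError("groups must share the bin axis")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p values")

    if bin_times_s is None:
        raise StatsError("bin_times_s required when passing raw matrices")
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    mask = (bin_times_s >= analysis_window[0]) & (bin_times_s < analysis_window[1])
    times = bin_times_s[mask]
    aw, bw = a[:, mask], b[:, mask]
    na, nb = aw.shape[0], bw.shape[0]
    x = np.vstack([aw, bw])
    n = na + nb

    observed = aw.mean(axis=0) - bw.mean(axis=0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # weight matrix trick: null[p] = sum_i w[p,i] * x[i], w = +1/na for the
    # rows assigned to A in permutation p and -1/nb otherwise
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    w = np.full((n_perm, n), -1.0 / nb)
    np.put_along_axis(w, order[:, :na], 1.0 / na, axis=1)
    null = w @ x                                     # (n_perm, n_bins)

    exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_adj = bh_fdr(p_raw)
    epochs = significant_epochs(p_adj, times, alpha=alpha, min_run=min_run)

    return PermutationResult(
        bin_times_s=times,
        observed_diff=observed,
        p_raw=p_raw,
        p_adj=p_adj,
        null_sd=null.std(axis=0, ddof=1),
        significant_epochs=epochs,
        n_perm=n_perm,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        alpha=alpha,
        min_run=min_run,
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_x - ECDF_y| with the
    asymptotic p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DevaluationResult:
    """Normalized lever-press distribution across valued/devalued test days.

    Each subject's valued proportion is presses(valued) / (valued + devalued);
    sensitivity to devaluation is a one-sample t of those proportions against
    0.5 (indifference)."""

    valued_proportion: np.ndarray
    devalued_proportion: np.ndarray
    mean: float
    sem: float
    t_statistic: float
    p_value: float
    n_subjects: int
    excluded_subjects: list = field(default_factory=list)
    degenerate: bool = False        # zero variance across subjects


def devaluation_index(
    valued_presses: np.ndarray, devalued_presses: np.ndarray
) -> DevaluationResult:
    v = np.asarray(valued_presses, dtype=float)
    d = np.asarray(devalued_presses, dtype=float)
    if v.shape != d.shape:
        raise StatsError("valued and devalued arrays must have equal length")
    total = v + d
    excluded = np.flatnonzero(total <= 0).tolist()
    if excluded:
        warnings.warn(f"excluding subject(s) with zero total presses: {excluded}")
    keep = total > 0
    v, d, total = v[keep], d[keep], total[keep]
    if v.size == 0:
        raise StatsError("no subjects with nonzero total presses")
    pv = v / total
    pd_ = d / total
    sd = pv.std(ddof=1) if pv.size > 1 else 0.0
    degenerate = bool(sd == 0)
    if degenerate or pv.size < 2:
        t_stat, p_val = np.nan, np.nan
        if degenerate:
            warnings.warn("zero variance in valued proportions; t undefined")
    else:
        t_stat, p_val = stats.ttest_1samp(pv, 0.5)
    return DevaluationResult(
        valued_proportion=pv,
        devalued_proportion=pd_,
        mean=float(pv.mean()),
        sem=float(sd / np.sqrt(pv.size)) if pv.size > 1 else np.nan,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_subjects=int(pv.size),
        excluded_subjects=excluded,
        degenerate=degenerate,
    )
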