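"""Skin-temperature threshold calibration against a behavioural reference.

The operating ``T_sk`` threshold is chosen iteratively:

1. sweep candidate thresholds (13–27 °C by default) and record, per
   threshold, the cohort arousal count and the arousal durations;
2. fit a continuous two-segment (breakpoint) regression of count on
   threshold — below the breakpoint, shallow warming events inflate the
   count, above it the count is threshold-insensitive;
3. compare each threshold's square-root-transformed durations against the
   behaviourally measured durations with Dunnett-style many-to-one
   comparisons (within-animal centering absorbs the repeated-measures
   structure);
4. select the smallest threshold that is above the breakpoint (reliable
   frequency) and duration-concordant with behaviour (non-significant
   Dunnett comparison) — the smallest, to stay maximally sensitive to
   shallow rewarming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .detect import Bout, TskTrace, detect_bouts_tsk

__all__ = [
    "SweepTable",
    "BreakpointFit",
    "DunnettResult",
    "NoValidThresholdError",
    "sweep_thresholds",
    "fit_breakpoint",
    "compare_durations",
    "select_threshold",
]

DEFAULT_GRID = tuple(range(13, 28))
_DUNNETT_MC_SEED = 20240307  # fixed internal seed: adjusted p-values are deterministic
_DUNNETT_MC_REPS = 20000


class NoValidThresholdError(RuntimeError):
    """No threshold satisfies both the frequency and duration criteria."""


@dataclass
class SweepTable:
    """Per-threshold arousal counts and durations over a cohort."""

    thresholds: np.ndarray
    counts: np.ndarray  # total arousals detected per threshold
    durations: dict  # threshold -> list of (bat_id, duration_min), uncensored

    def to_frame(self) -> pd.DataFrame:
        mean_h = [
            np.mean([d for _, d in self.durations[t]]) / 60.0
            if self.durations[t]
            else np.nan
            for t in self.thresholds
        ]
        return pd.DataFrame(
            {
                "threshold_c": self.thresholds,
                "n_arousals": self.counts,
                "mean_duration_h": mean_h,
            }
        )


@dataclass
class BreakpointFit:
    psi: float
    left_slope: float
    right_slope: float
    rss: float
    has_breakpoint: bool
    f_stat: float
    f_p: float
    segment_stats: dict = field(default_factory=dict)


@dataclass
class DunnettResult:
    """Many-to-one duration comparisons against the behavioural reference."""

    reference_mean: float  # transformed scale
    reference_n: int
    table: pd.DataFrame  # index threshold; columns mean_diff, t, p_adj
    alpha: float = 0.05
    levene_p: float = np.nan

    def nonsignificant(self) -> list[float]:
        return [float(t) for t in self.table.index if self.table.loc[t, "p_adj"] > self.alpha]


def sweep_thresholds(
    traces: list[TskTrace], grid=DEFAULT_GRID
) -> SweepTable:
    """Run the threshold detector at every grid value over the cohort.

    Counts include every detected arousal; durations come from uncensored
    arousals only.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if not traces:
        raise ValueError("empty cohort")
    counts = np.zeros(grid.size, dtype=int)
    durations: dict[float, list[tuple[str, float]]] = {float(t): [] for t in grid}
    for trace in traces:
        for i, thr in enumerate(grid):
            bouts = detect_bouts_tsk(trace, float(thr))
            arousals = [b for b in bouts if b.kind == "arousal"]
            counts[i] += len(arousals)
            durations[float(thr)].extend(
                (b.bat_id, b.duration_min) for b in arousals if not b.censored
            )
    return SweepTable(thresholds=grid, counts=counts, durations=durations)


def _two_segment_rss(x: np.ndarray, y: np.ndarray, psi: float):
    """Continuous two-segment least squares: y ~ 1 + x + (x - psi)_+."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta


def fit_breakpoint(x, y, resolution: float = 0.1, alpha: float = 0.05) -> BreakpointFit:
    """Breakpoint (segmented) regression of count on threshold.

    The join point ``psi`` is found by grid search at ``resolution`` °C over
    the interior of the x-range, minimizing the residual sum of squares of
    the continuous two-segment fit; candidates leaving fewer than 3 points
    on either side are excluded.  ``has_breakpoint`` is False when the
    two-segment fit fails an F-test (2 extra parameters) against a single
    straight line at level ``alpha``.  Per-segment slope F-tests allocate
    points at ``x ≤ floor(psi)`` to the left segment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 (x, y) points")
    order = np.argsort(x)
    x, y = x[order], y[order]

    # Single-line fit for the F-test.
    design1 = np.column_stack([np.ones_like(x), x])
    beta1, *_ = np.linalg.lstsq(design1, y, rcond=None)
    rss1 = float(np.sum((y - design1 @ beta1) ** 2))

    candidates = np.arange(x[0] + resolution, x[-1], resolution)
    candidates = [
        psi
        for psi in candidates
        if (x <= psi).sum() >= 3 and (x > psi).sum() >= 3
    ]
    if not candidates:
        raise ValueError("no admissible breakpoint candidates")
    best_psi, best_rss, best_beta = None, np.inf, None
    for psi in candidates:
        rss, beta = _two_segment_rss(x, y, psi)
        if rss < best_rss - 1e-12:
            best_rss, best_psi, best_beta = rss, psi, beta
    psi = float(best_psi)
    left_slope = float(best_beta[1])
    right_slope = float(best_beta[1] + best_beta[2])

    df2 = x.size - 4  # intercept, slope, slope change, psi
    tol = 1e-9 * max(1.0, float(y @ y))
    if rss1 <= tol:  # a single line already fits perfectly: no kink
        f_stat, f_p = 0.0, 1.0
    elif df2 <= 0 or best_rss <= tol:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = ((rss1 - best_rss) / 2.0) / (best_rss / df2)
        f_p = float(scipy.stats.f.sf(f_stat, 2, df2))
    has_breakpoint = f_p < alpha

    segment_stats = {}
    left = x <= np.floor(psi)
    for name, sel in (("left", left), ("right", ~left)):
        xs, ys = x[sel], y[sel]
        if xs.size >= 3 and np.ptp(xs) > 0:
            res = scipy.stats.linregress(xs, ys)
            fval = res.rvalue**2 / (1 - res.rvalue**2) * (xs.size - 2) \
                if abs(res.rvalue) < 1 else np.inf
            segment_stats[name] = {
                "slope": float(res.slope),
                "F": float(fval),
                "df": (1, xs.size - 2),
                "p": float(res.pvalue),
            }
    return BreakpointFit(
        psi=psi, left_slope=left_slope, right_slope=right_slope,
        rss=best_rss, has_breakpoint=bool(has_breakpoint),
        f_stat=float(f_stat), f_p=float(f_p), segment_stats=segment_stats,
    )


def _center_by_bat(frame: pd.DataFrame) -> pd.DataFrame:
    """Within-animal centering (plus grand mean) across all groups jointly."""
    grand = frame["value"].mean()
    bat_means = frame.groupby("bat_id")["value"].transform("mean")
    out = frame.copy()
    out["value"] = frame["value"] - bat_means + grand
    return out


def _dunnett_pvalues(
    tstats: np.ndarray, n: np.ndarray, n_ref: int, df: int, reps: int, seed: int
) -> np.ndarray:
    """Monte-Carlo adjusted two-sided p-values for many-to-one comparisons.

    Simulates the joint null of the K correlated t-statistics (shared
    reference group, shared pooled variance) and returns, for each observed
    statistic, the probability that max_k |T_k| exceeds it.
    """
    rng = np.random.default_rng(seed)
    z_ref = rng.standard_normal((reps, 1)) / np.sqrt(n_ref)
    z = rng.standard_normal((reps, n.size)) / np.sqrt(n)
    s = np.sqrt(rng.chisquare(df, (reps, 1)) / df)
    t_sim = (z - z_ref) / (s * np.sqrt(1.0 / n + 1.0 / n_ref))
    max_abs = np.abs(t_sim).max(axis=1)
    return np.array([(max_abs >= abs(t)).mean() for t in tstats])


def compare_durations(
    sweep: SweepTable,
    behaviour_durations: list[tuple[str, float]],
    transform=np.sqrt,
    alpha: float = 0.05,
    method: str = "montecarlo",
    mc_reps: int = _DUNNETT_MC_REPS,
) -> DunnettResult:
    """Dunnett-style comparison of each threshold's durations vs behaviour.

    Durations are transformed (square root by default, for normality of
    residuals), centered within animal to respect the repeated-measures
    structure, and each threshold group is compared against the behavioural
    reference with a family-wise adjustment: Monte-Carlo sampling of the
    many-to-one max-|t| null by default, or Bonferroni
    (``method="bonferroni"``).  A Levene variance-homogeneity check across
    groups is reported as ``levene_p`` (a warning, never a halt).
    """
    if not behaviour_durations:
        raise ValueError("behavioural reference is empty")
    rows = [("reference", b, float(d)) for b, d in behaviour_durations]
    for thr in sweep.thresholds:
        group = sweep.durations[float(thr)]
        if len(group) < 2:
            raise ValueError(f"threshold {thr}: fewer than 2 durations")
        rows.extend((f"{float(thr):g}", b, float(d)) for b, d in group)
    frame = pd.DataFrame(rows, columns=["group", "bat_id", "value"])
    frame["value"] = transform(frame["value"].to_numpy())
    frame = _center_by_bat(frame)

    groups = {g: sub["value"].to_numpy() for g, sub in frame.groupby("group")}
    ref = groups.pop("reference")
    labels = [f"{float(t):g}" for t in sweep.thresholds]
    n = np.array([groups[g].size for g in labels])
    means = np.array([groups[g].mean() for g in labels])
    k = len(labels)
    n_bats = frame["bat_id"].nunique()
    n_total = frame.shape[0]
    # Pooled within-group variance; centering spends (n_bats - 1) d.f.
    ss = float(((ref - ref.mean()) ** 2).sum()) + sum(
        float(((groups[g] - groups[g].mean()) ** 2).sum()) for g in labels
    )
    df = max(n_total - (k + 1) - (n_bats - 1), 1)
    s2 = ss / df
    if s2 <= 0:
        tstats = np.zeros(k)
        p_adj = np.ones(k)
    else:
        se = np.sqrt(s2 * (1.0 / n + 1.0 / ref.size))
        tstats = (means - ref.mean()) / se
        if method == "montecarlo":
            p_adj = _dunnett_pvalues(
                tstats, n, ref.size, df, mc_reps, _DUNNETT_MC_SEED
            )
        elif method == "bonferroni":
            p_adj = np.minimum(2 * scipy.stats.t.sf(np.abs(tstats), df) * k, 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")

    try:
        lev = scipy.stats.levene(ref, *[groups[g] for g in labels])
        levene_p = float(lev.pvalue)
        if levene_p < alpha:
            warnings.warn(
                f"variance homogeneity check failed (Levene p={levene_p:.3g})",
                stacklevel=2,
            )
    except Exception:  # degenerate groups
        levene_p = np.nan

    table = pd.DataFrame(
        {
            "mean_diff": means - ref.mean(),
            "t": tstats,
            "p_adj": np.clip(p_adj, 0.0, 1.0),
        },
        index=[float(t) for t in sweep.thresholds],
    )
    return DunnettResult(
        reference_mean=float(ref.mean()),
        reference_n=int(ref.size),
        table=table,
        alpha=alpha,
        levene_p=levene_p,
    )


def select_threshold(fit: BreakpointFit, dunnett: DunnettResult, grid=DEFAULT_GRID) -> float:
    """Pick the operating threshold.

    Frequency-valid thresholds lie strictly above the breakpoint (all of
    the grid when no breakpoint was found); duration-valid thresholds have
    a non-significant Dunnett comparison.  Returns the minimum of the
    intersection — the most sensitive threshold that is still reliable on
    both criteria.
    """
    grid = [float(t) for t in grid]
    freq_valid = {t for t in grid if (not fit.has_breakpoint) or t > fit.psi}
    dur_valid = set(dunnett.nonsignificant())
    valid = sorted(freq_valid & dur_valid)
    if not valid:
        raise NoValidThresholdError(
            "no threshold is both frequency- and duration-valid "
            f"(psi={fit.psi:.1f}, frequency-valid={sorted(freq_valid)}, "
            f"duration-valid={sorted(dur_valid)})"
        )
    return valid[0]
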