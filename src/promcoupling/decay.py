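"""Estimators for condition effects on mRNA levels and degradation.

After a global transcriptional arrest, the log2 ratio of mRNA levels
between two strains (e.g. a promoter-swapped strain SW and wild type WT)
declines linearly in time with slope -(k_SW - k_WT)/ln2, so an ordinary
least-squares fit of the ratio time course measures the degradation-rate
difference.  Combined with a known native half-life t1/2, the slope gives
the log2 degradation effect

    delta_deg = log2((1/t1/2 - slope) / (1/t1/2)),

which equals log2(k_SW / k_WT) under noiseless first-order kinetics.
Significance is assessed by a paired t-test over 20-minute interval
changes, pairing corresponding intervals between strains to absorb
gene-specific non-linearity along the course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: classification labels for the effect of swapping on degradation
INCREASED = "increased"
DECREASED = "decreased"
NOT_SIGNIFICANT = "not_significant"

#: fold-change threshold for calling a steady-state effect significant
STEADY_STATE_FOLD = 1.4


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # log2-ratio change per minute
    stderr: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class SwapEffect:
    """Per-gene summary of a swap (or any two-condition) experiment."""

    gene: str
    delta_swap: float
    slope: float
    slope_stderr: float
    delta_deg: float
    t_statistic: float
    p_value: float
    classification: str


def delta_swap(sw_gene: float, wt_gene: float, sw_ref: float, wt_ref: float) -> float:
    """log2 steady-state effect of swapping, normalized by a reference gene.

    delta_swap = log2[(SW_g / WT_g) / (SW_c / WT_c)]
    """
    for name, v in (("sw_gene", sw_gene), ("wt_gene", wt_gene),
                    ("sw_ref", sw_ref), ("wt_ref", wt_ref)):
        if not v > 0:
            raise ValueError(f"level {name} must be > 0, got {v}")
    return float(np.log2((sw_gene / wt_gene) / (sw_ref / wt_ref)))


def fit_decay_slope(timepoints, log2_ratios, *, mode: str = "pooled") -> SlopeFit:
    """Least-squares slope of the log2 strain ratio along the time course.

    ``timepoints`` and ``log2_ratios`` are flat, equal-length arrays;
    replicate measurements simply appear as repeated timepoints.  With
    ``mode='mean'`` the ratios are averaged per timepoint before fitting;
    the default pools all points into one fit.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(log2_ratios, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and log2_ratios must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("slope undefined: need >= 2 distinct timepoints")
    if mode == "mean":
        df = pd.DataFrame({"t": t, "y": y}).groupby("t", as_index=False).mean()
        t, y = df["t"].to_numpy(), df["y"].to_numpy()
    elif mode != "pooled":
        raise ValueError(f"mode must be 'pooled' or 'mean', got {mode!r}")
    res = stats.linregress(t, y)
    return SlopeFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


def delta_deg(slope: float, t_half: float) -> float:
    """log2 degradation-rate effect from the ratio slope and native half-life.

    delta_deg = log2((1/t_half - slope) / (1/t_half)); equals
    log2(k_SW/k_WT) for noiseless first-order decay when 1/t_half is the
    wild-type rate expressed per ln2 (i.e. t_half = ln2/k_WT).
    """
    if not t_half > 0:
        raise ValueError(f"t_half must be > 0, got {t_half}")
    base = 1.0 / t_half
    if not base - slope > 0:
        raise ValueError(
            f"1/t_half - slope = {base - slope:.4g} <= 0 implies a "
            "non-positive degradation rate"
        )
    return float(np.log2((base - slope) / base))


def interval_changes(levels: pd.Series, interval: float = 20.0) -> pd.Series:
    """Per-interval log2 changes Δ_{i,i+interval} = log2(m_{i+interval}/m_i).

    ``levels`` is indexed by time (minutes).  Intervals whose end point is
    missing from the grid are omitted with a warning.
    """
    lv = levels.sort_index()
    times = lv.index.to_numpy(dtype=float)
    out_idx, out = [], []
    for t0 in times:
        t1 = t0 + interval
        hit = np.isclose(times, t1)
        if hit.any():
            out_idx.append(t0)
            out.append(float(np.log2(lv.iloc[int(np.flatnonzero(hit)[0])]
                                     / lv.loc[t0])))
        elif t1 <= times.max():
            log.warning("no level at t=%g; interval starting at %g omitted", t1, t0)
    return pd.Series(out, index=pd.Index(out_idx, name="time_min"), name="delta")


def _interval_deltas(course: pd.DataFrame, interval: float) -> pd.DataFrame:
    """Interval changes per replicate for one gene's course.

    ``course`` has columns (replicate, time_min, level); returns a frame
    indexed by (replicate, time_min of interval start).
    """
    parts = []
    for rep, grp in course.groupby("replicate"):
        s = grp.set_index("time_min")["level"]
        d = interval_changes(s, interval)
        d.index = pd.MultiIndex.from_product(
            [[rep], d.index], names=["replicate", "start"]
        )
        parts.append(d)
    return pd.concat(parts).to_frame()


def paired_interval_test(
    sw_course: pd.DataFrame,
    wt_course: pd.DataFrame,
    interval: float = 20.0,
):
    """Paired t-test on 20-minute interval changes between two strains.

    Both inputs are tidy courses for a single gene with columns
    (replicate, time_min, level), already reference-normalized.  Interval
    changes are paired by (replicate, interval start); the two-sided
    one-sample t-test is applied to the differences SW - WT.  All-zero
    differences return (0, 1) by convention.
    """
    d_sw = _interval_deltas(sw_course, interval)
    d_wt = _interval_deltas(wt_course, interval)
    joined = d_sw.join(d_wt, how="inner", lsuffix="_sw", rsuffix="_wt").dropna()
    diffs = (joined["delta_sw"] - joined["delta_wt"]).to_numpy()
    return paired_differences_test(diffs)


def paired_differences_test(diffs) -> tuple[float, float]:
    """Two-sided one-sample t-test of paired differences against zero."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError(
            f"need >= 2 paired differences, got {diffs.size}"
        )
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def classify_effect(slope: float, p_value: float, alpha: float = 0.05) -> str:
    """Direction call for the degradation effect of swapping.

    A negative ratio slope means the swapped strain's mRNA decays faster,
    i.e. the swapped sequence increases degradation.
    """
    if not (np.isfinite(slope) and np.isfinite(p_value)):
        raise ValueError("slope and p_value must be finite")
    if p_value > alpha or slope == 0.0:
        return NOT_SIGNIFICANT
    return INCREASED if slope < 0 else DECREASED


def steady_state_effect_significance(
    delta_swap_value: float, threshold: float = float(np.log2(STEADY_STATE_FOLD))
) -> bool:
    """Steady-state effect call: fold-change >= 1.4 in either direction.

    ``threshold`` is in log2 units (default log2 1.4 ~ 0.4854).
    """
    if not np.isfinite(delta_swap_value):
        raise ValueError("delta_swap must be finite")
    return bool(abs(delta_swap_value) >= threshold)


def exponential_fit_quality(times, levels) -> float:
    """R^2 of log2(level) against time — fit to first-order decay.

    Requires >= 3 timepoints; a perfect exponential gives 1.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(levels, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("fit quality undefined with < 3 distinct timepoints")
    if not np.all(m > 0):
        raise ValueError("levels must be > 0")
    res = stats.linregress(t, np.log2(m))
    return float(res.rvalue**2)


def select_best_fit(scores: pd.Series, fraction: float = 0.12) -> pd.Index:
    """Genes in the top ``fraction`` by exponential-fit R^2.

    Keeps round(n * fraction) genes (at least 1 when fraction > 0).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    s = scores.dropna()
    k = max(1, int(round(len(s) * fraction)))
    return s.sort_values(ascending=False).index[:k]


# ---------------------------------------------------------------------------
# course-level drivers operating on the tidy time-course table
# ---------------------------------------------------------------------------

def normalized_ratio_course(
    table: pd.DataFrame,
    gene: str,
    reference: str,
    *,
    sw: str = "SW",
    wt: str = "WT",
) -> pd.DataFrame:
    """Reference-normalized log2(SW/WT) course for one gene.

    ``table`` is the tidy (gene, strain, replicate, time_min, level) table.
    Returns columns (replicate, time_min, log2_ratio) where

        log2_ratio = log2[(SW_g / WT_g) / (SW_c / WT_c)]

    computed per replicate and timepoint.
    """
    piv = table.pivot_table(
        index=["replicate", "time_min"], columns=["gene", "strain"],
        values="level",
    )
    try:
        ratio = np.log2(
            (piv[(gene, sw)] / piv[(gene, wt)])
            / (piv[(reference, sw)] / piv[(reference, wt)])
        )
    except KeyError as exc:
        raise ValueError(f"missing course for {exc.args[0]!r}") from exc
    return ratio.rename("log2_ratio").reset_index()


def relative_level_course(
    table: pd.DataFrame, gene: str, reference: str, strain: str
) -> pd.DataFrame:
    """Per-replicate levels of ``gene`` relative to ``reference`` (m_i)."""
    piv = table[table["strain"] == strain].pivot_table(
        index=["replicate", "time_min"], columns="gene", values="level"
    )
    rel = (piv[gene] / piv[reference]).rename("level").reset_index()
    return rel


def analyze_gene(
    table: pd.DataFrame,
    gene: str,
    reference: str,
    t_half: float,
    *,
    sw: str = "SW",
    wt: str = "WT",
    interval: float = 20.0,
    alpha: float = 0.05,
    mode: str = "pooled",
) -> SwapEffect:
    """Full per-gene analysis of a two-strain arrest experiment."""
    ratios = normalized_ratio_course(table, gene, reference, sw=sw, wt=wt)
    at0 = ratios[ratios["time_min"] == 0.0]["log2_ratio"]
    if at0.empty:
        raise ValueError("time 0 required for the steady-state effect")
    d_swap = float(at0.mean())

    fit = fit_decay_slope(ratios["time_min"], ratios["log2_ratio"], mode=mode)
    try:
        d_deg = delta_deg(fit.slope, t_half)
    except ValueError:
        d_deg = float("nan")
        log.warning("gene %s: slope %.4g implies non-positive rate at "
                    "t_half %.3g; delta_deg undefined", gene, fit.slope, t_half)

    sw_rel = relative_level_course(table, gene, reference, sw)
    wt_rel = relative_level_course(table, gene, reference, wt)
    t_stat, p = paired_interval_test(sw_rel, wt_rel, interval)
    return SwapEffect(
        gene=gene,
        delta_swap=d_swap,
        slope=fit.slope,
        slope_stderr=fit.stderr,
        delta_deg=d_deg,
        t_statistic=t_stat,
        p_value=p,
        classification=classify_effect(fit.slope, p, alpha),
    )


def paired_interval_tests_bulk(
    table: pd.DataFrame,
    *,
    sw: str = "SW",
    wt: str = "WT",
    interval: float = 20.0,
) -> pd.DataFrame:
    """Vectorized paired interval tests for every gene in a tidy table.

    Levels are used as-is (pass reference-normalized or noise-relative
    levels).  Equivalent to calling :func:`paired_interval_test` per gene;
    implemented with one array t-test for cohort-scale simulations.
    """
    piv = table.pivot_table(
        index="gene", columns=["strain", "replicate", "time_min"], values="level"
    )
    times = np.array(sorted({c[2] for c in piv.columns}))
    starts = [t0 for t0 in times if np.isclose(times, t0 + interval).any()]
    reps = sorted({c[1] for c in piv.columns})

    diff_cols = []
    for rep in reps:
        for t0 in starts:
            t1 = times[np.isclose(times, t0 + interval)][0]
            d_sw = np.log2(piv[(sw, rep, t1)] / piv[(sw, rep, t0)])
            d_wt = np.log2(piv[(wt, rep, t1)] / piv[(wt, rep, t0)])
            diff_cols.append(d_sw - d_wt)
    diffs = np.column_stack(diff_cols)
    if diffs.shape[1] < 2:
        raise ValueError("need >= 2 paired differences per gene")
    res = stats.ttest_1samp(diffs, 0.0, axis=1)
    out = pd.DataFrame(
        {"t_statistic": res.statistic, "p_value": res.pvalue}, index=piv.index
    )
    zero = np.all(np.isclose(diffs, 0.0), axis=1)
    out.loc[zero, ["t_statistic", "p_value"]] = [0.0, 1.0]
    return out
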