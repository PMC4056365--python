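"""Total/nascent turnover comparison between two conditions.

With a metabolic-labeling window of length t_label, the nascent fraction
of an mRNA pool encodes its turnover: new/total = 1 - exp(-k_deg*t_label).
Comparing two conditions (cell types or species) over an ortholog map,
the centered log2 ratios of total (Δtotal) and nascent (Δnew) mRNA levels
separate transcriptional from degradation changes: Δnew - Δtotal > 0
indicates faster degradation in condition 2.

Three generative models predict distinct class-conditional shifts for
genes called differentially degraded:

I   independent transcription — Δnew unshifted, Δtotal strongly shifted
    opposite to the degradation change;
II  measurement noise — moderate, mirror-image shifts of Δnew (up) and
    Δtotal (down) for the higher-degradation class;
III coupled transcription (over-compensation) — Δnew and Δtotal both
    shifted in the SAME direction as the degradation change.

``shift_report`` measures the class-conditional medians and calls the
pattern by explicit sign/magnitude checks (never a p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from ._rng import child_rng

log = logging.getLogger(__name__)

LN2 = np.log(2.0)

HIGHER_IN_2 = "higher_in_2"
HIGHER_IN_1 = "higher_in_1"
UNCHANGED = "unchanged"
DEG_CLASSES = (HIGHER_IN_2, HIGHER_IN_1, UNCHANGED)

#: minimal |median shift difference| (log2) treated as a real shift
SHIFT_EPS = 0.05
#: |ΔnewShift| / |ΔtotalShift| below this ratio reads as "Δnew unshifted"
INDEPENDENT_RATIO = 0.3


@dataclass
class DeltaResult:
    """Centered log2 ratios per ortholog pair plus filter provenance."""

    table: pd.DataFrame  # index pair id; gene_1, gene_2, delta_total, delta_new
    n_input: int
    n_nonpositive: int
    n_low_intensity: int
    n_large_delta: int
    center: str | None


def compute_deltas(
    total_1: pd.DataFrame,
    total_2: pd.DataFrame,
    new_1: pd.DataFrame,
    new_2: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    *,
    center: str | None = "median",
    min_intensity_quantile: float = 0.05,
    max_abs_delta: float = 5.0,
) -> DeltaResult:
    """Δtotal and Δnew per ortholog pair from four genes x replicates matrices.

    Replicates are averaged per gene; pairs whose mean total intensity
    falls below the ``min_intensity_quantile`` quantile of either
    condition are filtered out before the Δ computation, as are pairs with
    a non-positive mean in any matrix; pairs with |Δ| > ``max_abs_delta``
    (pre-centering) in either Δ are dropped as implausible.  Each Δ vector
    is finally centered to zero (median by default, 'mean' optional, None
    to skip).
    """
    om = ortholog_map.reset_index(drop=True)
    if not {"gene_1", "gene_2"} <= set(om.columns):
        raise ValueError("ortholog_map needs columns gene_1, gene_2")
    n_input = len(om)

    m_t1 = total_1.mean(axis=1).reindex(om["gene_1"]).to_numpy()
    m_n1 = new_1.mean(axis=1).reindex(om["gene_1"]).to_numpy()
    m_t2 = total_2.mean(axis=1).reindex(om["gene_2"]).to_numpy()
    m_n2 = new_2.mean(axis=1).reindex(om["gene_2"]).to_numpy()

    with np.errstate(invalid="ignore"):
        positive = (m_t1 > 0) & (m_t2 > 0) & (m_n1 > 0) & (m_n2 > 0)
    n_nonpositive = int(n_input - positive.sum())

    lo_1 = np.nanquantile(total_1.mean(axis=1), min_intensity_quantile)
    lo_2 = np.nanquantile(total_2.mean(axis=1), min_intensity_quantile)
    intense = positive & (m_t1 >= lo_1) & (m_t2 >= lo_2)
    n_low = int(positive.sum() - intense.sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        d_total = np.log2(m_t2 / m_t1)
        d_new = np.log2(m_n2 / m_n1)
    within = intense & (np.abs(d_total) <= max_abs_delta) \
        & (np.abs(d_new) <= max_abs_delta)
    n_large = int(intense.sum() - within.sum())

    table = pd.DataFrame(
        {
            "gene_1": om["gene_1"],
            "gene_2": om["gene_2"],
            "delta_total": d_total,
            "delta_new": d_new,
        }
    )[within].reset_index(drop=True)

    if center is not None:
        if center == "median":
            table["delta_total"] -= table["delta_total"].median()
            table["delta_new"] -= table["delta_new"].median()
        elif center == "mean":
            table["delta_total"] -= table["delta_total"].mean()
            table["delta_new"] -= table["delta_new"].mean()
        else:
            raise ValueError("center must be 'median', 'mean' or None")

    return DeltaResult(
        table=table,
        n_input=n_input,
        n_nonpositive=n_nonpositive,
        n_low_intensity=n_low,
        n_large_delta=n_large,
        center=center,
    )


def turnover_from_labeling(new, total, t_label: float):
    """Degradation rate and half-life from the nascent/total ratio.

    k_deg = -ln(1 - new/total) / t_label;  t_half = ln2 / k_deg.
    Elementwise over arrays; new >= total or new <= 0 (noise artifacts)
    give NaN.
    """
    if not t_label > 0:
        raise ValueError(f"t_label must be > 0, got {t_label}")
    new = np.asarray(new, dtype=float)
    total = np.asarray(total, dtype=float)
    frac = np.where((new > 0) & (new < total) & (total > 0), new / total, np.nan)
    with np.errstate(invalid="ignore"):
        k = -np.log(1.0 - frac) / t_label
        t_half = LN2 / k
    return k, t_half


def estimate_half_lives(data: synthetic.LabelingData) -> pd.DataFrame:
    """Per-gene half-life estimates for both conditions of a labeling run."""
    out = {}
    for cond, new, total in (
        ("1", data.new_1, data.total_1),
        ("2", data.new_2, data.total_2),
    ):
        _, t_half = turnover_from_labeling(
            new.mean(axis=1).to_numpy(), total.mean(axis=1).to_numpy(),
            data.t_label,
        )
        out[f"t_half_{cond}"] = pd.Series(t_half, index=new.index)
    return pd.DataFrame(out)


def classify_differential_degradation(
    comparison: pd.DataFrame, fold: float = 1.75
) -> pd.Series:
    """Dual-criterion differential-degradation call per ortholog pair.

    ``comparison`` needs columns delta_total, delta_new, t_half_1,
    t_half_2.  A gene is 'higher_in_2' only when BOTH criteria agree:
    t_half_1/t_half_2 >= fold AND (Δnew - Δtotal) >= log2(fold); mirrored
    for 'higher_in_1'.  Missing half-lives leave the gene unclassifiable
    (NaN).
    """
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    needed = {"delta_total", "delta_new", "t_half_1", "t_half_2"}
    missing = needed - set(comparison.columns)
    if missing:
        raise ValueError(f"comparison missing columns: {sorted(missing)}")
    th = np.log2(fold)
    dd = comparison["delta_new"] - comparison["delta_total"]
    ratio = comparison["t_half_1"] / comparison["t_half_2"]
    cls = pd.Series(UNCHANGED, index=comparison.index, dtype=object)
    cls[(ratio >= fold) & (dd >= th)] = HIGHER_IN_2
    cls[(1.0 / ratio >= fold) & (-dd >= th)] = HIGHER_IN_1
    cls[~np.isfinite(ratio) | ~np.isfinite(dd)] = np.nan
    return cls.rename("deg_class")


@dataclass
class ShiftReport:
    """Class-conditional medians of Δtotal/Δnew and the model-pattern call."""

    medians: pd.DataFrame  # index deg_class; columns delta_total, delta_new
    class_counts: pd.Series
    pattern_call: str  # 'independent' | 'noise' | 'coupled' | 'no_call'
    checks: dict = field(default_factory=dict)

    @property
    def d_new(self) -> float:
        return self.checks.get("d_new", float("nan"))

    @property
    def d_total(self) -> float:
        return self.checks.get("d_total", float("nan"))


def shift_report(observed: pd.DataFrame) -> ShiftReport:
    """Medians of Δtotal and Δnew per degradation class + pattern call.

    The call compares D_new = median Δnew(higher_in_2) - median
    Δnew(higher_in_1) with the analogous D_total:

    - both clearly positive            -> 'coupled'   (Model III)
    - D_total < 0, |D_new| small       -> 'independent' (Model I)
    - D_total < 0, D_new positive and
      comparable in magnitude          -> 'noise'     (Model II)

    "Small" means |D_new| < INDEPENDENT_RATIO * |D_total|; "clear" means
    exceeding SHIFT_EPS log2 units.  With fewer than two populated
    differential classes no call is made.
    """
    if "deg_class" not in observed.columns:
        raise ValueError("observed table needs a deg_class column")
    med_rows, counts = {}, {}
    for cls in DEG_CLASSES:
        sub = observed[observed["deg_class"] == cls]
        counts[cls] = len(sub)
        med_rows[cls] = {
            "delta_total": sub["delta_total"].median() if len(sub) else np.nan,
            "delta_new": sub["delta_new"].median() if len(sub) else np.nan,
        }
    medians = pd.DataFrame(med_rows).T
    class_counts = pd.Series(counts, name="n")

    if counts[HIGHER_IN_2] == 0 or counts[HIGHER_IN_1] == 0:
        log.warning("a differential class is empty; no pattern call possible")
        return ShiftReport(medians, class_counts, "no_call",
                           {"reason": "empty differential class"})

    d_new = medians.loc[HIGHER_IN_2, "delta_new"] \
        - medians.loc[HIGHER_IN_1, "delta_new"]
    d_total = medians.loc[HIGHER_IN_2, "delta_total"] \
        - medians.loc[HIGHER_IN_1, "delta_total"]
    checks = {
        "d_new": float(d_new),
        "d_total": float(d_total),
        "both_shifts_positive": bool(d_new > SHIFT_EPS and d_total > SHIFT_EPS),
        "total_shift_negative": bool(d_total < -SHIFT_EPS),
        "new_shift_small": bool(abs(d_new) < INDEPENDENT_RATIO * abs(d_total)),
    }
    if checks["both_shifts_positive"]:
        call = "coupled"
    elif checks["total_shift_negative"] and checks["new_shift_small"]:
        call = "independent"
    elif checks["total_shift_negative"] and d_new > SHIFT_EPS:
        call = "noise"
    else:
        call = "no_call"
    return ShiftReport(medians, class_counts, call, checks)


def model_distributions(
    scenario: synthetic.CouplingScenario,
    *,
    t_label: float = 60.0,
    fold: float = 1.75,
    n_replicates: int = 3,
    replicate_sd: float = 0.1,
    capture_sd: float = 0.5,
    center: str | None = "median",
    t_half_median: float = 240.0,
    t_half_sd_log2: float = 0.8,
) -> pd.DataFrame:
    """Simulate a labeling cohort under one model and classify it.

    Runs simulate_kinetics -> simulate_labeling -> compute_deltas ->
    half-life estimation -> classify_differential_degradation and returns
    the comparison table (delta_total, delta_new, t_half_1, t_half_2,
    deg_class) whose class-conditional distributions realize the model's
    predicted signature.  The scenario's sd_noise enters as per-assay
    probe distortion; replicate noise is a separate, smaller layer.
    """
    kin = synthetic.simulate_kinetics(
        scenario, t_half_median=t_half_median, t_half_sd_log2=t_half_sd_log2
    )
    data = synthetic.simulate_labeling(
        kin,
        t_label,
        sd_noise=replicate_sd,
        sd_assay=scenario.sd_noise,
        capture_sd=capture_sd,
        n_replicates=n_replicates,
        seed=scenario.seed,
    )
    return comparison_table(data, center=center, fold=fold)


def comparison_table(
    data: synthetic.LabelingData,
    *,
    center: str | None = "median",
    fold: float = 1.75,
    min_intensity_quantile: float = 0.05,
    max_abs_delta: float = 5.0,
) -> pd.DataFrame:
    """Deltas + half-lives + degradation class for a labeling dataset."""
    res = compute_deltas(
        data.total_1, data.total_2, data.new_1, data.new_2, data.ortholog_map,
        center=center, min_intensity_quantile=min_intensity_quantile,
        max_abs_delta=max_abs_delta,
    )
    hl = estimate_half_lives(data)
    tab = res.table.copy()
    tab["t_half_1"] = hl["t_half_1"].reindex(tab["gene_1"]).to_numpy()
    tab["t_half_2"] = hl["t_half_2"].reindex(tab["gene_2"]).to_numpy()
    tab["deg_class"] = classify_differential_degradation(tab, fold=fold)
    return tab


def nonortholog_null(
    data: synthetic.LabelingData,
    *,
    seed: int = 0,
    center: str | None = "median",
    fold: float = 1.75,
) -> ShiftReport:
    """Shift report after shuffling the ortholog map (non-ortholog pairs).

    Random re-pairing destroys the within-gene link between the two
    conditions, so apparent degradation differences behave like the
    noise-model signature.
    """
    rng = child_rng(seed, "ortholog_shuffle")
    om = data.ortholog_map.copy().reset_index(drop=True)
    om["gene_2"] = rng.permutation(om["gene_2"].to_numpy())
    shuffled = synthetic.LabelingData(
        total_1=data.total_1, total_2=data.total_2,
        new_1=data.new_1, new_2=data.new_2,
        ortholog_map=om, t_label=data.t_label,
    )
    return shift_report(comparison_table(shuffled, center=center, fold=fold))


def degradation_level_correlation(
    delta_deg: pd.Series,
    delta_level: pd.Series,
    *,
    method: str = "spearman",
    fit_scores: pd.Series | None = None,
    best_fit_fraction: float | None = None,
) -> tuple[float, float, int]:
    """Correlation between degradation-rate changes and mRNA-level changes.

    Positive Δdeg means faster degradation in condition 2; a positive
    correlation with Δlevel therefore indicates transcriptional
    over-compensation of degradation changes.  ``delta_level`` may come
    from an independent dataset (control mode); with ``fit_scores`` and
    ``best_fit_fraction`` the analysis is restricted to the genes whose
    arrest courses fit exponential decay best.

    Returns (correlation, p_value, n_genes).
    """
    joined = pd.concat(
        {"deg": delta_deg, "lvl": delta_level}, axis=1, join="inner"
    ).dropna()
    if best_fit_fraction is not None:
        if fit_scores is None:
            raise ValueError("best_fit_fraction requires fit_scores")
        from .decay import select_best_fit

        keep = select_best_fit(fit_scores, best_fit_fraction)
        joined = joined.loc[joined.index.intersection(keep)]
    if len(joined) < 10:
        raise ValueError(f"need >= 10 genes with both values, got {len(joined)}")
    if method == "spearman":
        r, p = stats.spearmanr(joined["deg"], joined["lvl"])
    elif method == "pearson":
        r, p = stats.pearsonr(joined["deg"], joined["lvl"])
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(r), float(p), len(joined)
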