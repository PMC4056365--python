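"""Adjacent gene-pair architecture analysis.

Divergently transcribed neighbours share their upstream intergenic region
and hence, potentially, promoter elements; convergent and tandem
neighbours do not.  Comparing the similarity of per-gene degradation
statistics across the three architectures — and across bins of intergenic
length or co-expression — isolates promoter sharing from generic effects
of genomic proximity.  The shared-regulator analysis makes the same
comparison for non-adjacent genes that are bound by the same transcription
factors, stratifying on expression similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ARCHITECTURES = ("divergent", "convergent", "tandem")

MIN_PAIRS = 3  # below this a correlation is reported as undefined


def classify_pairs(annotation: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Classify consecutive gene pairs by strand architecture.

    ``annotation`` needs columns (gene, chrom, start, end, strand) in
    0-based half-open coordinates.  Genes are sorted by (chrom, start);
    each pair of consecutive non-overlapping genes on a chromosome becomes
    one record.  Overlapping consecutive genes are excluded and counted in
    the report.

    Returns (pairs, report) where pairs has columns (chrom, left_gene,
    right_gene, architecture, intergenic_length).
    """
    required = {"gene", "chrom", "start", "end", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = ~annotation["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"invalid strand values: {annotation.loc[bad, 'strand'].unique()}"
        )
    if (annotation["start"] >= annotation["end"]).any():
        raise ValueError("every gene must have start < end")

    rows, n_overlap = [], 0
    for chrom, grp in annotation.sort_values(["chrom", "start"]).groupby("chrom"):
        g = grp.reset_index(drop=True)
        for i in range(len(g) - 1):
            left, right = g.iloc[i], g.iloc[i + 1]
            gap = int(right["start"] - left["end"])
            if gap < 0:
                n_overlap += 1
                continue
            if left["strand"] == right["strand"]:
                arch = "tandem"
            elif left["strand"] == "-":
                arch = "divergent"
            else:
                arch = "convergent"
            rows.append((chrom, left["gene"], right["gene"], arch, gap))
    pairs = pd.DataFrame(
        rows,
        columns=["chrom", "left_gene", "right_gene", "architecture",
                 "intergenic_length"],
    )
    return pairs, {"n_pairs": len(pairs), "n_overlapping_excluded": n_overlap}


def _corr(x, y, method: str):
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


def pair_correlation(
    pairs: pd.DataFrame,
    values: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of a per-gene statistic between pair members.

    ``values`` is indexed by gene id.  Pairs with a missing member are
    dropped and counted.  Architectures with fewer than three usable pairs
    get NaN correlations (flagged by n_pairs, never silently zero).

    Returns a frame indexed by architecture with columns (n_pairs,
    n_dropped, r, p).
    """
    out = []
    for arch in ARCHITECTURES:
        sub = pairs[pairs["architecture"] == arch]
        lv = values.reindex(sub["left_gene"]).to_numpy(dtype=float)
        rv = values.reindex(sub["right_gene"]).to_numpy(dtype=float)
        ok = np.isfinite(lv) & np.isfinite(rv)
        n_drop = int(len(sub) - ok.sum())
        if ok.sum() < MIN_PAIRS:
            if len(sub):
                log.warning(
                    "architecture %s: only %d usable pairs, correlation "
                    "undefined", arch, int(ok.sum()),
                )
            out.append((arch, int(ok.sum()), n_drop, np.nan, np.nan))
            continue
        r, p = _corr(lv[ok], rv[ok], method)
        out.append((arch, int(ok.sum()), n_drop, r, p))
    return pd.DataFrame(
        out, columns=["architecture", "n_pairs", "n_dropped", "r", "p"]
    ).set_index("architecture")


def coexpression_covariate(expression: pd.DataFrame, pair) -> float:
    """Pearson correlation of the two pair members' expression profiles.

    ``expression`` is genes x conditions; ``pair`` is any record with
    left_gene/right_gene.  Returns NaN when a member is missing.
    """
    left, right = pair["left_gene"], pair["right_gene"]
    if left not in expression.index or right not in expression.index:
        return float("nan")
    x = expression.loc[left].to_numpy(dtype=float)
    y = expression.loc[right].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 conditions for a co-expression covariate")
    return float(stats.pearsonr(x, y)[0])


def coexpression_covariates(expression: pd.DataFrame, pairs: pd.DataFrame) -> pd.Series:
    """Vector of co-expression covariates aligned with ``pairs`` rows."""
    return pd.Series(
        [coexpression_covariate(expression, row) for _, row in pairs.iterrows()],
        index=pairs.index,
        name="coexpression",
    )


def equal_count_bins(covariate: pd.Series, n_bins: int, order: pd.Index) -> pd.Series:
    """Equal-count bin labels (0..n_bins-1) by covariate rank.

    Ties and equal ranks are broken by the stable ``order`` of the pairs
    (genomic order), so bin sizes differ by at most one.
    """
    cov = covariate.loc[order]
    if n_bins > cov.notna().sum():
        raise ValueError(
            f"n_bins ({n_bins}) exceeds number of pairs with a covariate "
            f"({int(cov.notna().sum())})"
        )
    usable = cov.dropna()
    pos = np.argsort(usable.to_numpy(), kind="stable")
    labels = pd.Series(np.nan, index=cov.index, name="bin")
    chunks = np.array_split(np.arange(len(usable)), n_bins)
    for b, chunk in enumerate(chunks):
        labels.loc[usable.index[pos[chunk]]] = b
    return labels


def bin_pairs(
    pairs: pd.DataFrame,
    values: pd.Series,
    covariate: pd.Series,
    n_bins: int,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-bin, per-architecture pair correlations along a covariate.

    Pairs are binned into equal-count bins of the covariate *within each
    architecture* (so every architecture's bins are comparable in size),
    then :func:`pair_correlation` is applied per bin.

    Returns a frame with columns (architecture, bin, n_pairs, cov_lo,
    cov_hi, r, p).
    """
    if len(covariate) != len(pairs):
        raise ValueError("covariate must align with pairs")
    out = []
    for arch in ARCHITECTURES:
        mask = pairs["architecture"] == arch
        if not mask.any():
            continue
        sub = pairs[mask].sort_values(["chrom", "left_gene"])
        labels = equal_count_bins(covariate[mask], n_bins, sub.index)
        for b in range(n_bins):
            in_bin = labels.index[labels == b]
            bp = pairs.loc[in_bin]
            cv = covariate.loc[in_bin]
            row = pair_correlation(bp, values, method).loc[arch]
            out.append((arch, b, int(row["n_pairs"]), float(cv.min()),
                        float(cv.max()), row["r"], row["p"]))
    return pd.DataFrame(
        out, columns=["architecture", "bin", "n_pairs", "cov_lo", "cov_hi",
                      "r", "p"],
    )


@dataclass
class SharedRegulatorReport:
    """Outcome of the shared-regulator pair comparison.

    per_stratum : one row per expression-similarity stratum with group
        sizes, median |Δdeg difference| per group, the one-sided
        rank-sum p (shared pairs more similar) and the effect direction.
    pooled_p : Stouffer combination of the per-stratum tests.
    pooled_direction : +1 if shared-regulator pairs are more similar in
        degradation overall, -1 otherwise.
    """

    per_stratum: pd.DataFrame
    pooled_p: float
    pooled_direction: int
    n_shared_pairs: int
    n_control_pairs: int


def shared_regulator_analysis(
    regulator_matrix: pd.DataFrame,
    deg_change: pd.Series,
    expr_change: pd.Series,
    *,
    min_shared: int = 3,
    n_strata: int = 5,
    min_group: int = 10,
) -> SharedRegulatorReport:
    """Compare degradation-change similarity of co-regulated vs control pairs.

    Gene pairs sharing at least ``min_shared`` regulators are compared with
    pairs sharing none.  Pair similarity is the absolute difference of the
    per-gene statistic (smaller = more similar).  To control for expression
    similarity, pairs are stratified into equal-count bins of
    |Δexpr difference| and the rank-sum comparison runs within each
    stratum; the pooled p combines strata by Stouffer's method weighted by
    sqrt(stratum size).
    """
    m = regulator_matrix.to_numpy(dtype=int)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("regulator matrix must be binary")
    genes = regulator_matrix.columns.to_numpy()
    deg = deg_change.reindex(genes).to_numpy(dtype=float)
    expr = expr_change.reindex(genes).to_numpy(dtype=float)
    if np.isnan(deg).any() or np.isnan(expr).any():
        raise ValueError("deg_change/expr_change must cover all matrix genes")

    shared_counts = m.T @ m  # genes x genes
    iu = np.triu_indices(len(genes), k=1)
    counts = shared_counts[iu]
    is_shared = counts >= min_shared
    is_control = counts == 0
    n_shared, n_control = int(is_shared.sum()), int(is_control.sum())
    if n_shared == 0 or n_control == 0:
        raise ValueError(
            f"empty pair group (shared >= {min_shared}: {n_shared}, "
            f"no shared regulator: {n_control})"
        )
    for name, n in (("shared", n_shared), ("control", n_control)):
        if n < min_group:
            log.warning("%s-regulator group has only %d pairs", name, n)

    keep = is_shared | is_control
    i, j = iu[0][keep], iu[1][keep]
    pairs = pd.DataFrame(
        {
            "deg_diff": np.abs(deg[i] - deg[j]),
            "expr_diff": np.abs(expr[i] - expr[j]),
            "group": np.where(is_shared[keep], "shared", "control"),
        }
    )
    # equal-count expression-similarity strata over the pooled pairs
    pairs["stratum"] = pd.qcut(
        pairs["expr_diff"].rank(method="first"), n_strata, labels=False
    )

    rows, zs, ws = [], [], []
    for s, grp in pairs.groupby("stratum"):
        a = grp.loc[grp["group"] == "shared", "deg_diff"].to_numpy()
        b = grp.loc[grp["group"] == "control", "deg_diff"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append((s, len(a), len(b), np.nan, np.nan, np.nan, 0))
            continue
        # one-sided: shared pairs have SMALLER |deg difference|
        u, p = stats.mannwhitneyu(a, b, alternative="less")
        direction = int(np.sign(np.median(b) - np.median(a))) or 0
        rows.append((s, len(a), len(b), float(np.median(a)),
                     float(np.median(b)), float(p), direction))
        zs.append(stats.norm.isf(min(max(p, 1e-300), 1 - 1e-16)))
        ws.append(np.sqrt(len(a) + len(b)))
    per_stratum = pd.DataFrame(
        rows,
        columns=["stratum", "n_shared", "n_control", "median_diff_shared",
                 "median_diff_control", "p_one_sided", "direction"],
    )
    if not zs:
        raise ValueError("no stratum had both groups populated")
    z = float(np.dot(ws, zs) / np.linalg.norm(ws))
    pooled_p = float(stats.norm.sf(z))
    pooled_dir = 1 if z > 0 else -1
    return SharedRegulatorReport(
        per_stratum=per_stratum,
        pooled_p=pooled_p,
        pooled_direction=pooled_dir,
        n_shared_pairs=n_shared,
        n_control_pairs=n_control,
    )
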