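"""Synthetic data with known ground-truth kinetics.

Every pipeline input has a generator here: first-order mRNA kinetics under
two conditions (with transcription and degradation changes drawn from one
of three generative models), transcription-arrest decay time courses,
metabolic-labeling total/nascent readouts, genome layouts with
shared-promoter coupling between divergent neighbours, and binary
regulator-target matrices with regulon-correlated effects.

Conventions: time in minutes, rates in 1/min, all ratios and noise terms in
log2 units, genomic coordinates 0-based half-open, strands '+'/'-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

LN2 = np.log(2.0)

MODELS = ("independent", "noise", "coupled")

ARCHITECTURES = ("divergent", "convergent", "tandem")


@dataclass(frozen=True)
class GeneKinetics:
    """First-order kinetics of one gene in one condition.

    steady-state level = k_syn / k_deg; half-life = ln2 / k_deg.
    """

    gene_id: str
    k_syn: float  # transcripts/min
    k_deg: float  # 1/min
    condition: str = "WT"

    def __post_init__(self) -> None:
        if not self.k_syn > 0:
            raise ValueError(f"k_syn must be > 0, got {self.k_syn}")
        if not self.k_deg > 0:
            raise ValueError(f"k_deg must be > 0, got {self.k_deg}")

    @property
    def steady_state(self) -> float:
        return self.k_syn / self.k_deg

    @property
    def half_life(self) -> float:
        return LN2 / self.k_deg


@dataclass(frozen=True)
class CouplingScenario:
    """Generative model for paired transcription/degradation changes.

    model
        'independent' — Δsyn and Δdeg drawn independently;
        'noise'       — no true changes, apparent differences are pure
                        measurement distortion;
        'coupled'     — Δsyn = beta · Δdeg + residual (promoter-driven
                        compensation; beta > 1 over-compensates).
    beta
        coupling slope in log2 transcription change per log2 degradation
        change (dimensionless).
    sd_bio
        spread of true biological effects, log2 units.
    sd_noise
        per-gene, per-assay, per-condition measurement distortion (probe
        efficiency differences), log2 units.
    """

    model: str
    n_genes: int
    beta: float = 0.0
    sd_bio: float = 0.7
    sd_noise: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; valid options: {MODELS}"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.sd_bio < 0 or self.sd_noise < 0:
            raise ValueError("sd_bio and sd_noise must be >= 0")
        if self.model == "independent" and self.beta != 0.0:
            raise ValueError("model='independent' forces beta = 0")


@dataclass
class GenomeLayout:
    """Synthetic genome: gene records plus ground-truth pairing.

    genes   : DataFrame (gene, chrom, start, end, strand)
    pairs   : DataFrame (chrom, left_gene, right_gene, architecture,
              intergenic_length, coupling_eff)
    changes : DataFrame (gene, delta_syn, delta_deg) — true log2 changes
    expression : DataFrame genes x conditions, used for co-expression binning
    shared_promoter_groups : divergent pairs driven by one latent promoter
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    changes: pd.DataFrame
    expression: pd.DataFrame
    shared_promoter_groups: list = field(default_factory=list)


@dataclass
class LabelingData:
    """Total and nascent expression matrices for two conditions.

    Matrices are genes x replicates; ortholog_map pairs condition-1 gene
    ids with condition-2 gene ids (identity for synthetic cohorts).
    """

    total_1: pd.DataFrame
    total_2: pd.DataFrame
    new_1: pd.DataFrame
    new_2: pd.DataFrame
    ortholog_map: pd.DataFrame
    t_label: float


def simulate_kinetics(
    scenario: CouplingScenario,
    *,
    t_half_median: float = 240.0,
    t_half_sd_log2: float = 0.8,
    k_syn_median: float = 1.0,
    k_syn_sd_log2: float = 1.5,
    gene_prefix: str = "g",
) -> pd.DataFrame:
    """Draw paired two-condition kinetics for each gene under a scenario.

    Baseline (condition 1) half-lives and synthesis rates are log-normal
    around the given medians; condition-2 rates are the baseline scaled by
    2**Δ with Δ drawn according to ``scenario.model``.

    Returns a DataFrame with columns gene, k_syn_1, k_deg_1, k_syn_2,
    k_deg_2, delta_syn_true, delta_deg_true.
    """
    rng = child_rng(scenario.seed, "kinetics")
    n = scenario.n_genes
    genes = [f"{gene_prefix}{i:05d}" for i in range(n)]

    t_half = t_half_median * 2.0 ** rng.normal(0.0, t_half_sd_log2, n)
    k_deg_1 = LN2 / t_half
    k_syn_1 = k_syn_median * 2.0 ** rng.normal(0.0, k_syn_sd_log2, n)

    if scenario.model == "noise":
        d_deg = np.zeros(n)
        d_syn = np.zeros(n)
    else:
        d_deg = rng.normal(0.0, scenario.sd_bio, n)
        resid = rng.normal(0.0, scenario.sd_bio, n)
        if scenario.model == "coupled":
            d_syn = scenario.beta * d_deg + resid
        else:  # independent
            d_syn = resid

    return pd.DataFrame(
        {
            "gene": genes,
            "k_syn_1": k_syn_1,
            "k_deg_1": k_deg_1,
            "k_syn_2": k_syn_1 * 2.0**d_syn,
            "k_deg_2": k_deg_1 * 2.0**d_deg,
            "delta_syn_true": d_syn,
            "delta_deg_true": d_deg,
        }
    )


def _check_kinetics_frame(kinetics: pd.DataFrame) -> None:
    needed = {"gene", "k_syn_1", "k_deg_1", "k_syn_2", "k_deg_2"}
    missing = needed - set(kinetics.columns)
    if missing:
        raise ValueError(f"kinetics table missing columns: {sorted(missing)}")
    rates = kinetics[["k_syn_1", "k_deg_1", "k_syn_2", "k_deg_2"]].to_numpy()
    if not np.all(rates > 0):
        raise ValueError("all synthesis and degradation rates must be > 0")


def simulate_decay_timecourse(
    kinetics: pd.DataFrame,
    timepoints,
    *,
    reference_gene: str | None = None,
    sd_noise: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    strain_labels: tuple[str, str] = ("WT", "SW"),
) -> pd.DataFrame:
    """Relative mRNA levels after transcriptional arrest.

    level(g, t) = (k_syn/k_deg) * exp(-k_deg * t) * 2**eps with
    eps ~ Normal(0, sd_noise) independent per measurement.  The reference
    gene, if named, must be one of the simulated genes — it is generated
    identically and is only special to downstream normalization.

    Returns a tidy table (gene, strain, replicate, time_min, level).
    """
    _check_kinetics_frame(kinetics)
    t = np.asarray(list(timepoints), dtype=float)
    if t.size < 2:
        raise ValueError("need at least two timepoints")
    if np.any(t < 0):
        raise ValueError(f"negative timepoint in {t.tolist()}")
    if 0.0 not in t:
        raise ValueError("timepoints must include 0 (arrest onset)")
    if reference_gene is not None and reference_gene not in set(kinetics["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in kinetics table")

    rng = child_rng(seed, "decay_timecourse")
    frames = []
    for label, syn_col, deg_col in (
        (strain_labels[0], "k_syn_1", "k_deg_1"),
        (strain_labels[1], "k_syn_2", "k_deg_2"),
    ):
        syn = kinetics[syn_col].to_numpy()
        deg = kinetics[deg_col].to_numpy()
        # genes x replicates x timepoints
        clean = (syn / deg)[:, None, None] * np.exp(
            -deg[:, None, None] * t[None, None, :]
        )
        eps = rng.normal(0.0, sd_noise, size=(len(syn), n_replicates, t.size))
        levels = clean * 2.0**eps
        idx = pd.MultiIndex.from_product(
            [kinetics["gene"], range(1, n_replicates + 1), t],
            names=["gene", "replicate", "time_min"],
        )
        df = pd.DataFrame({"level": levels.ravel()}, index=idx).reset_index()
        df.insert(1, "strain", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_labeling(
    kinetics: pd.DataFrame,
    t_label: float,
    *,
    sd_noise: float = 0.0,
    sd_assay: float = 0.0,
    capture_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> LabelingData:
    """Metabolic-labeling readout: total and nascent mRNA per condition.

    Noise-free quantities per gene and condition:

        total = k_syn / k_deg
        new   = (k_syn / k_deg) * (1 - exp(-k_deg * t_label))

    so new <= total always, and new/total = 1 - exp(-k_deg*t_label) encodes
    turnover.  Three multiplicative log-normal layers are available:

    sd_noise   per measurement (gene x condition x assay x replicate);
    sd_assay   per gene x condition x assay, surviving replicate averaging
               (probe-efficiency distortion — the content of the 'noise'
               generative model);
    capture_sd per gene, applied to the nascent assay only and shared by
               the two conditions of the same gene (labeled-RNA capture
               efficiency is sequence-dependent, so orthologs share it; it
               cancels in ortholog comparisons but not between unrelated
               genes).
    """
    _check_kinetics_frame(kinetics)
    if not t_label > 0:
        raise ValueError(f"t_label must be > 0, got {t_label}")

    rng = child_rng(seed, "labeling")
    genes = kinetics["gene"].tolist()
    n = len(genes)
    reps = [f"rep{i}" for i in range(1, n_replicates + 1)]
    capture = rng.normal(0.0, capture_sd, n) if capture_sd > 0 else np.zeros(n)

    mats = {}
    for cond, syn_col, deg_col in (
        ("1", "k_syn_1", "k_deg_1"),
        ("2", "k_syn_2", "k_deg_2"),
    ):
        syn = kinetics[syn_col].to_numpy()
        deg = kinetics[deg_col].to_numpy()
        total = syn / deg
        new = total * (1.0 - np.exp(-deg * t_label))
        for assay, clean in (("total", total), ("new", new)):
            distort = rng.normal(0.0, sd_assay, n) if sd_assay > 0 else 0.0
            eps = rng.normal(0.0, sd_noise, size=(n, n_replicates))
            vals = clean[:, None] * 2.0 ** (np.atleast_1d(distort)[:, None] + eps)
            if assay == "new":
                vals = vals * 2.0 ** capture[:, None]
            mats[f"{assay}_{cond}"] = pd.DataFrame(vals, index=genes, columns=reps)

    omap = pd.DataFrame({"gene_1": genes, "gene_2": genes})
    return LabelingData(
        total_1=mats["total_1"],
        total_2=mats["total_2"],
        new_1=mats["new_1"],
        new_2=mats["new_2"],
        ortholog_map=omap,
        t_label=t_label,
    )


def simulate_genome(
    n_divergent: int,
    n_convergent: int,
    n_tandem: int,
    *,
    intergenic_median: float = 400.0,
    intergenic_sd_log2: float = 1.0,
    gene_length: tuple[int, int] = (500, 2000),
    coupling_strength: float = 0.0,
    length_coupling_scale: float | None = None,
    effect_sd: float = 0.5,
    n_expression_conditions: int = 50,
    seed: int = 0,
) -> GenomeLayout:
    """Lay out adjacent gene pairs of the three architectures.

    Each pair occupies its own synthetic chromosome, so annotation
    adjacency coincides exactly with the intended pairing.  Divergent pairs
    share a latent promoter-activity change that contributes weight
    ``coupling_strength`` (as a variance fraction, via sqrt-weights) to
    BOTH genes' Δsyn and Δdeg; convergent and tandem pairs get fully
    independent changes.  If ``length_coupling_scale`` is set, the
    effective coupling of a divergent pair decays as
    exp(-intergenic_length / scale), emulating weaker promoter sharing
    across longer intergenic regions.
    """
    for name, v in (("n_divergent", n_divergent), ("n_convergent", n_convergent),
                    ("n_tandem", n_tandem)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError(
            f"coupling_strength must be in [0, 1], got {coupling_strength}"
        )

    rng = child_rng(seed, "genome")
    strand_of = {
        "divergent": ("-", "+"),
        "convergent": ("+", "-"),
        "tandem": ("+", "+"),
    }
    counts = {
        "divergent": n_divergent,
        "convergent": n_convergent,
        "tandem": n_tandem,
    }

    gene_rows, pair_rows, groups = [], [], []
    gene_ids, couplings = [], []
    gid = 0
    for arch in ARCHITECTURES:
        for i in range(counts[arch]):
            chrom = f"chr_{arch[:3]}_{i:05d}"
            left_id, right_id = f"g{gid:05d}", f"g{gid + 1:05d}"
            gid += 2
            len_l, len_r = rng.integers(gene_length[0], gene_length[1], 2)
            inter = max(1, int(round(
                intergenic_median * 2.0 ** rng.normal(0.0, intergenic_sd_log2)
            )))
            start_l = 1000
            end_l = start_l + int(len_l)
            start_r = end_l + inter
            end_r = start_r + int(len_r)
            s_l, s_r = strand_of[arch]
            gene_rows.append((left_id, chrom, start_l, end_l, s_l))
            gene_rows.append((right_id, chrom, start_r, end_r, s_r))

            if arch == "divergent":
                c = coupling_strength
                if length_coupling_scale is not None:
                    c *= float(np.exp(-inter / length_coupling_scale))
                groups.append((left_id, right_id))
            else:
                c = 0.0
            pair_rows.append((chrom, left_id, right_id, arch, inter, c))
            gene_ids.extend([left_id, right_id])
            couplings.extend([c, c])

    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand"]
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["chrom", "left_gene", "right_gene", "architecture",
                 "intergenic_length", "coupling_eff"],
    )

    # true per-gene changes: shared pair latent + gene-specific components
    n_pairs = len(pairs)
    c_pair = pairs["coupling_eff"].to_numpy()
    z_shared = rng.normal(0.0, 1.0, n_pairs)
    d = {}
    for which in ("syn", "deg"):
        own = rng.normal(0.0, 1.0, 2 * n_pairs)
        shared = np.repeat(z_shared, 2)
        c = np.asarray(couplings)
        d[which] = effect_sd * (np.sqrt(c) * shared + np.sqrt(1.0 - c) * own)
    changes = pd.DataFrame(
        {"gene": gene_ids, "delta_syn": d["syn"], "delta_deg": d["deg"]}
    )

    # expression profiles with the same shared/own variance split
    erng = child_rng(seed, "expression_profiles")
    ncond = n_expression_conditions
    shared_prof = np.repeat(erng.normal(0.0, 1.0, (n_pairs, ncond)), 2, axis=0)
    own_prof = erng.normal(0.0, 1.0, (2 * n_pairs, ncond))
    c = np.asarray(couplings)[:, None]
    expr = np.sqrt(c) * shared_prof + np.sqrt(1.0 - c) * own_prof
    expression = pd.DataFrame(
        expr, index=gene_ids,
        columns=[f"cond{j + 1}" for j in range(ncond)],
    )

    return GenomeLayout(
        genes=genes,
        pairs=pairs,
        changes=changes,
        expression=expression,
        shared_promoter_groups=groups,
    )


def simulate_regulator_matrix(
    n_genes: int,
    n_regulators: int,
    targets_per_regulator: int,
    *,
    coupling: float = 0.8,
    effect_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary regulator-target matrix plus regulon-correlated gene effects.

    Each regulator carries a latent activity change; a gene's true
    degradation and expression changes mix the (normalized) sum of its
    regulators' latents with gene-specific noise, with variance fraction
    ``coupling`` assigned to the shared part.  Genes sharing regulators
    therefore have correlated changes, giving the shared-regulator pair
    analysis a recoverable signal.

    Returns (matrix, gene_stats): matrix is regulators x genes with 0/1
    entries; gene_stats has columns gene, delta_deg, delta_expr.
    """
    if min(n_genes, n_regulators, targets_per_regulator) < 1:
        raise ValueError("all counts must be >= 1")
    if targets_per_regulator > n_genes:
        raise ValueError(
            f"targets_per_regulator ({targets_per_regulator}) exceeds "
            f"n_genes ({n_genes})"
        )
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")

    rng = child_rng(seed, "regulators")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    regs = [f"reg{r:03d}" for r in range(n_regulators)]
    m = np.zeros((n_regulators, n_genes), dtype=int)
    for r in range(n_regulators):
        m[r, rng.choice(n_genes, size=targets_per_regulator, replace=False)] = 1
    matrix = pd.DataFrame(m, index=regs, columns=genes)

    z = rng.normal(0.0, 1.0, n_regulators)
    n_regs_per_gene = m.sum(axis=0)
    shared = np.zeros(n_genes)
    hit = n_regs_per_gene > 0
    shared[hit] = (m[:, hit] * z[:, None]).sum(axis=0) / np.sqrt(
        n_regs_per_gene[hit]
    )
    stats = {}
    for which in ("deg", "expr"):
        own = rng.normal(0.0, 1.0, n_genes)
        eff = np.where(
            hit,
            np.sqrt(coupling) * shared + np.sqrt(1.0 - coupling) * own,
            own,
        )
        stats[which] = effect_sd * eff
    gene_stats = pd.DataFrame(
        {"gene": genes, "delta_deg": stats["deg"], "delta_expr": stats["expr"]}
    )
    return matrix, gene_stats
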