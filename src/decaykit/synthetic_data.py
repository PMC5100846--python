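"""Synthetic datasets with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised against data with known
ground truth: coding sequences with a controlled wobble-position GC
content (GC3) and planted poly-proline runs; gene x predictor tables in
which the degradation rate constant depends linearly on transformed
predictors with Gaussian noise at a chosen R^2; categorical group effects
on top of the continuous model; and shutoff qPCR Ct tables generated from
exponential decay at known rate constants observed through Ct-scale
noise relative to a stable reference gene.

Every generator is a pure function of its configuration (including the
seed): identical inputs give identical outputs, and each returns the
realized truth needed to score recovery without regeneration.

Default conditions: 4,000 genes (the complete-case scale of genome-wide
yeast degradation datasets), a linear model explaining R^2 = 0.43 of rate
variance, rates centred near 0.15 min^-1, and qPCR time courses over six
time points in triplicate with Ct noise SD 0.2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .predictor_table import PredictorTable, TransformSpec, assemble
from .regression_model import CategoricalAnnotation
from .sequence_features import (
    CODON_TO_AA,
    CodingSequence,
    SYNONYMOUS_FAMILIES,
)

__all__ = [
    "PredictorSpec",
    "CategorySpec",
    "CdsConfig",
    "QpcrConfig",
    "GeneratorConfig",
    "gen_cds",
    "gen_predictor_table",
    "gen_categorical",
    "gen_qpcr",
]


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal distribution (on the transformed scale) and true effect.

    ``mean``/``sd`` describe the predictor on its transformed scale, where
    it is modeled as normal; ``beta`` is the true effect on the rate
    constant (min^-1) per SD of the transformed predictor.
    """

    name: str
    transform: str = "none"
    mean: float = 0.0
    sd: float = 1.0
    beta: float = 0.0


@dataclass(frozen=True)
class CategorySpec:
    label: str
    prevalence: float
    shift: float = 0.0  # additive effect on the rate constant, min^-1

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass(frozen=True)
class CdsConfig:
    """Coding-sequence generator settings (lengths in codons)."""

    length_meanlog: float = np.log(350.0)
    length_sdlog: float = 0.45
    min_codons: int = 30
    max_codons: int = 2000
    target_gc3: float = 0.45
    gc3_tolerance: float = 0.02
    optimal_codon_fraction: float = 0.5
    polyproline_fraction: float = 0.1
    polyproline_run: int = 4


@dataclass(frozen=True)
class QpcrConfig:
    """Shutoff time-course settings: true decay constants and Ct noise."""

    k_true: Mapping[str, float] = field(
        default_factory=lambda: {"GFP2": 0.035, "GFP3": 0.025, "GFP4": 0.015}
    )
    times: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0)
    replicates: int = 3
    ct_noise_sd: float = 0.2
    ref_ct_mean: float = 15.0
    gene_ct0_mean: float = 16.0


def _default_predictors() -> tuple[PredictorSpec, ...]:
    # mirrors the flavor of genome-wide yeast predictor sets: lengths and
    # densities log-normal, GC proportions and nTE already ~normal
    return (
        PredictorSpec("coding_length", "log10", mean=3.05, sd=0.25, beta=0.020),
        PredictorSpec("ribosome_density", "log10_plus1", mean=1.2, sd=0.35, beta=-0.012),
        PredictorSpec("abundance", "log10", mean=1.0, sd=0.6, beta=0.0),
        PredictorSpec("gc3", "none", mean=0.42, sd=0.06, beta=-0.008),
        PredictorSpec("cai", "log10", mean=-0.8, sd=0.15, beta=-0.012),
        PredictorSpec("nte", "none", mean=1.0, sd=0.15, beta=-0.008),
        PredictorSpec("dg", "none", mean=-250.0, sd=90.0, beta=0.010),
    )


@dataclass
class GeneratorConfig:
    """Settings for all four generators; a pure function of these + seed."""

    seed: int = 0
    n_genes: int = 4000
    predictors: tuple[PredictorSpec, ...] = field(default_factory=_default_predictors)
    intercept: float = 0.15  # mean rate constant, min^-1
    sigma: float | None = None  # residual SD of rates; exclusive with target R^2
    target_r_squared: float | None = 0.43
    predictor_correlation: np.ndarray | None = None  # on the transformed scale
    categories: tuple[CategorySpec, ...] = ()
    rbp_categories: tuple[CategorySpec, ...] = ()
    category_mode: str = "independent"  # or "exclusive"
    cds: CdsConfig = field(default_factory=CdsConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        if (self.sigma is None) == (self.target_r_squared is None):
            raise ValueError("set exactly one of sigma and target_r_squared")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.target_r_squared is not None and not 0 < self.target_r_squared < 1:
            raise ValueError("target_r_squared must be in (0, 1)")


# --- coding sequences -------------------------------------------------------

_AAS = sorted(SYNONYMOUS_FAMILIES)  # 20 amino acids
_GC_CODONS = {
    aa: tuple(c for c in codons if c[2] in "GC")
    for aa, codons in SYNONYMOUS_FAMILIES.items()
}
_AT_CODONS = {
    aa: tuple(c for c in codons if c[2] in "AT")
    for aa, codons in SYNONYMOUS_FAMILIES.items()
}
#: designated most-adapted codon per family (first GC-class codon)
OPTIMAL_CODONS = {
    aa: (_GC_CODONS[aa][0] if _GC_CODONS[aa] else codons[0])
    for aa, codons in SYNONYMOUS_FAMILIES.items()
}


def _one_cds(
    rng: np.random.Generator, cfg: CdsConfig, plant_polyproline: bool
) -> tuple[str, dict]:
    n_codons = int(
        np.clip(
            np.round(rng.lognormal(cfg.length_meanlog, cfg.length_sdlog)),
            cfg.min_codons,
            cfg.max_codons,
        )
    )
    # amino-acid sequence: fixed start Met, uniform body
    aas = ["M"] + list(rng.choice(_AAS, size=n_codons - 1))
    run = cfg.polyproline_run
    if plant_polyproline:
        pos = int(rng.integers(1, n_codons - run))
        aas[pos : pos + run] = ["P"] * run
    else:
        # break accidental proline runs so planted genes are exactly the
        # polyproline-positive set
        count = 0
        for i, aa in enumerate(aas):
            count = count + 1 if aa == "P" else 0
            if count >= run:
                aas[i] = "A"
                count = 0
    # third-position class assignment to hit the GC3 target
    fixed_gc = [i for i, aa in enumerate(aas) if not _AT_CODONS[aa]]  # M, W
    flippable = [i for i, aa in enumerate(aas) if _AT_CODONS[aa] and _GC_CODONS[aa]]
    n_target = int(round(cfg.target_gc3 * n_codons))
    lo, hi = len(fixed_gc), len(fixed_gc) + len(flippable)
    if not lo <= n_target <= hi:
        raise ValueError(
            f"GC3 target {cfg.target_gc3} infeasible for this sequence; "
            f"feasible range [{lo / n_codons:.3f}, {hi / n_codons:.3f}]"
        )
    n_flip = n_target - len(fixed_gc)
    gc_positions = set(fixed_gc) | set(
        rng.choice(flippable, size=n_flip, replace=False).tolist()
    )
    codons = []
    n_optimal = 0
    for i, aa in enumerate(aas):
        pool = _GC_CODONS[aa] if i in gc_positions else _AT_CODONS[aa]
        opt = OPTIMAL_CODONS[aa]
        if opt in pool and rng.random() < cfg.optimal_codon_fraction:
            codon = opt
        else:
            codon = pool[int(rng.integers(len(pool)))]
        if codon == opt:
            n_optimal += 1
        codons.append(codon)
    seq = "".join(codons) + "TAA"
    truth = {
        "n_codons": n_codons,
        "gc3": len(gc_positions) / n_codons,
        "polyproline": plant_polyproline,
        "optimal_fraction": n_optimal / n_codons,
    }
    return seq, truth


def gen_cds(config: GeneratorConfig) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate coding sequences at a target GC3 with planted proline runs.

    Sequences start ATG, end TAA, and contain no internal stops. The
    realized GC3 (terminal stop excluded) hits the target exactly up to
    rounding on the codon count; a declared fraction of genes receives a
    planted run of >= 4 consecutive proline codons, and accidental runs
    in the remaining genes are broken, so the poly-proline classifier's
    positive set equals the planted set.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config.cds
    records, rows = [], []
    planted = rng.random(config.n_genes) < cfg.polyproline_fraction
    for i in range(config.n_genes):
        gene = f"g{i:04d}"
        seq, truth = _one_cds(rng, cfg, bool(planted[i]))
        records.append(CodingSequence(gene, seq))
        rows.append({"gene_id": gene, **truth})
    return records, pd.DataFrame(rows).set_index("gene_id")


# --- predictor tables -------------------------------------------------------


def _inverse_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return x
    if transform == "log10":
        return 10.0**x
    if transform == "log10_plus1":
        return 10.0**x - 1.0
    raise ValueError(transform)


def gen_predictor_table(config: GeneratorConfig) -> tuple[PredictorTable, dict]:
    """Generate a predictor table with a known linear rate model.

    Predictors are multivariate normal on the transformed scale with the
    configured correlation (identity by default), back-transformed to
    original units, and assembled through the regular pipeline (so the
    table's columns equal the latent transformed values to rounding). The
    response is k = intercept + sum(beta_j z_j) + eps with z the
    standardized transformed predictors and eps Gaussian; when a target
    R^2 is set, the residual SD is solved from var(beta'z) so the
    population R^2 equals the target. The few rates that come out
    non-positive have their noise redrawn (rates are physically positive).

    Returns the table and a truth dict with the betas on both scales, the
    residual SD, and the realized response components.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.predictors
    p = len(specs)
    corr = (
        np.eye(p)
        if config.predictor_correlation is None
        else np.asarray(config.predictor_correlation, dtype=float)
    )
    if corr.shape != (p, p):
        raise ValueError("correlation matrix shape does not match predictors")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("predictor correlation matrix is not positive definite") from exc
    n = config.n_genes
    z = rng.standard_normal((n, p)) @ chol.T
    beta = np.array([s.beta for s in specs])
    eta = z @ beta
    var_eta = float(beta @ corr @ beta)
    if config.target_r_squared is not None:
        r2 = config.target_r_squared
        if var_eta == 0 and r2 > 0:
            raise ValueError("target R^2 > 0 requires a non-zero beta")
        sigma = float(np.sqrt(var_eta * (1 - r2) / r2)) if var_eta > 0 else 1.0
    else:
        sigma = float(config.sigma)
    eps = rng.normal(0.0, sigma, size=n)
    k = config.intercept + eta + eps
    for _ in range(100):  # redraw noise for non-physical (<= 0) rates
        bad = k <= 0
        if not bad.any():
            break
        eps[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        k[bad] = config.intercept + eta[bad] + eps[bad]
    if (k <= 0).any():
        raise ValueError("could not generate positive rates; shrink sigma or betas")
    genes = [f"g{i:04d}" for i in range(n)]
    sources = []
    transforms = []
    for j, s in enumerate(specs):
        transformed = s.mean + s.sd * z[:, j]
        original = _inverse_transform(transformed, s.transform)
        sources.append((s.name, dict(zip(genes, original))))
        transforms.append(TransformSpec(s.name, s.transform))
    table = assemble(sources, transforms, dict(zip(genes, k)))
    expected_r2 = var_eta / (var_eta + sigma**2) if var_eta > 0 else 0.0
    truth = {
        "beta_sd_units": {s.name: s.beta for s in specs},
        "beta_transformed_scale": {s.name: s.beta / s.sd for s in specs},
        "intercept": config.intercept,
        "sigma": sigma,
        "expected_r_squared": expected_r2,
        "seed": config.seed,
        "n_genes": n,
    }
    return table, truth


# --- categorical annotations ------------------------------------------------


def gen_categorical(
    config: GeneratorConfig, table: PredictorTable
) -> tuple[list[CategoricalAnnotation], PredictorTable, dict]:
    """Assign category labels and shift the response by category effects.

    GO-style labels come from ``config.categories``, RBP-target labels
    from ``config.rbp_categories``. In "independent" mode each gene joins
    each category by an independent Bernoulli draw (genes can be
    multi-label); in "exclusive" mode a single multinomial draw assigns at
    most one GO label per gene (prevalences must then sum to < 1). The
    returned table has the response shifted by the summed effects of each
    gene's categories; the truth records memberships and shifts.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = table.genes
    n = len(genes)
    go_members: dict[str, np.ndarray] = {}
    if config.category_mode == "exclusive":
        prev = [c.prevalence for c in config.categories]
        if sum(prev) > 1:
            raise ValueError("exclusive-mode prevalences sum to > 1")
        probs = prev + [1 - sum(prev)]
        draws = rng.choice(len(probs), size=n, p=probs)
        for i, cat in enumerate(config.categories):
            go_members[cat.label] = draws == i
    elif config.category_mode == "independent":
        for cat in config.categories:
            go_members[cat.label] = rng.random(n) < cat.prevalence
    else:
        raise ValueError(f"unknown category_mode {config.category_mode!r}")
    rbp_members = {
        cat.label: rng.random(n) < cat.prevalence for cat in config.rbp_categories
    }
    shift = np.zeros(n)
    for cat in config.categories:
        shift += cat.shift * go_members[cat.label]
    for cat in config.rbp_categories:
        shift += cat.shift * rbp_members[cat.label]
    response = table.response + pd.Series(shift, index=table.data.index)
    if (response.dropna() <= 0).any():
        raise ValueError(
            "category shifts drove some rate constants non-positive; "
            "use smaller shifts or a larger intercept"
        )
    annotations = [
        CategoricalAnnotation(
            gene_id=g,
            go_slim_terms=frozenset(
                lbl for lbl, mask in go_members.items() if mask[i]
            ),
            rbp_targets=frozenset(
                lbl for lbl, mask in rbp_members.items() if mask[i]
            ),
        )
        for i, g in enumerate(genes)
    ]
    truth = {
        "mode": config.category_mode,
        "categories": [asdict(c) for c in config.categories],
        "rbp_categories": [asdict(c) for c in config.rbp_categories],
        "members": {lbl: [genes[i] for i in np.flatnonzero(mask)]
                    for lbl, mask in {**go_members, **rbp_members}.items()},
    }
    return annotations, table.with_response(response), truth


# --- qPCR time courses ------------------------------------------------------


def gen_qpcr(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate shutoff qPCR Ct observations from known decay constants.

    True abundance decays as A(t) = A0 exp(-k t); the gene Ct rises by
    k*t/ln2 cycles accordingly, and both gene and reference Ct get
    independent Gaussian noise on the Ct scale (multiplicative on
    abundance). Replicates model independent cultures: each replicate
    draws its own noise.
    """
    cfg = config.qpcr
    if cfg.ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if len(cfg.times) < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(config.seed + 2)
    ln2 = np.log(2.0)
    rows = []
    for gene in sorted(cfg.k_true):
        k = cfg.k_true[gene]
        if k <= 0:
            raise ValueError(f"k_true must be positive (gene {gene})")
        for rep in range(1, cfg.replicates + 1):
            for t in cfg.times:
                ct_gene = cfg.gene_ct0_mean + k * t / ln2 + rng.normal(0, cfg.ct_noise_sd)
                ct_ref = cfg.ref_ct_mean + rng.normal(0, cfg.ct_noise_sd)
                rows.append(
                    {
                        "gene": gene,
                        "time": float(t),
                        "replicate": rep,
                        "ct_gene": ct_gene,
                        "ct_ref": ct_ref,
                    }
                )
    truth = {
        "k_true": dict(cfg.k_true),
        "ct_noise_sd": cfg.ct_noise_sd,
        "times": list(cfg.times),
        "replicates": cfg.replicates,
        "seed": config.seed,
    }
    return pd.DataFrame(rows), truth
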