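"""Transcriptional-shutoff qRT-PCR decay analysis.

After transcription of a construct is repressed (e.g. with doxycycline on
a tet-off promoter), its mRNA level decays exponentially. Levels are
quantified by qPCR relative to a stable reference gene in the same sample
(delta-Ct: Y = 2^(ct_ref - ct_gene)), normalized to the level at shutoff
(t = 0), and the decay constant k is the negative slope of ln(Y) against
time by least squares over all replicate points. Uncertainty comes from a
case-resampling bootstrap with percentile intervals; constructs are
compared through the bootstrap distribution of the difference in k.

The delta-Ct sign convention matters: a decaying transcript must show
decreasing normalized Y, which the standard convention 2^(ct_ref -
ct_gene) guarantees. The reversed exponent is available as
``convention="as_printed"`` for matching legacy spreadsheets; the choice
is recorded on every result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "QPCR_COLUMNS",
    "DecayFit",
    "relative_abundance",
    "normalize_to_t0",
    "aggregate_replicates",
    "fit_decay",
    "bootstrap_ci",
    "compare_decay",
    "analyze_timecourse",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: expected long-format columns of a Ct table
QPCR_COLUMNS = ("gene", "time", "replicate", "ct_gene", "ct_ref")


@dataclass
class DecayFit:
    """A fitted exponential decay: k (min^-1) with optional bootstrap CI."""

    gene: str
    k: float
    intercept: float  # ln Y at t = 0
    half_life: float
    n_points: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    k_draws: np.ndarray | None = field(default=None, repr=False)
    band: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def rising(self) -> bool:
        """True when the fitted signal increases over time (k <= 0)."""
        return self.k <= 0


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["time"] < 0).any():
        raise ValueError("time since shutoff must be >= 0")
    for col in ("ct_gene", "ct_ref"):
        vals = df[col]
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{col} must be finite and positive")


def relative_abundance(df: pd.DataFrame, convention: str = "standard") -> pd.DataFrame:
    """Add the delta-Ct relative level Y to a long-format Ct table.

    standard: Y = 2^(ct_ref - ct_gene); as_printed: Y = 2^(ct_gene -
    ct_ref) (the reciprocal). The convention used is stored in
    ``df.attrs["convention"]``.
    """
    if convention not in ("standard", "as_printed"):
        raise ValueError(f"unknown convention {convention!r}")
    _validate(df)
    out = df.copy()
    delta = out["ct_ref"] - out["ct_gene"]
    out["Y"] = 2.0 ** (delta if convention == "standard" else -delta)
    out.attrs["convention"] = convention
    return out


def normalize_to_t0(df: pd.DataFrame) -> pd.DataFrame:
    """Divide each replicate's Y by that replicate's value at t = 0.

    Every (gene, replicate) series must contain a t = 0 observation; after
    normalization t = 0 maps to exactly 1. Idempotent.
    """
    if "Y" not in df.columns:
        raise ValueError("run relative_abundance first (no Y column)")
    out = df.copy()
    norm = np.empty(len(out))
    for (gene, rep), idx in out.groupby(["gene", "replicate"]).groups.items():
        sub = out.loc[idx]
        at_zero = sub.loc[sub["time"] == 0, "Y"]
        if at_zero.empty:
            raise ValueError(f"no t=0 observation for gene {gene!r} replicate {rep}")
        norm[out.index.get_indexer(idx)] = sub["Y"].to_numpy() / float(at_zero.iloc[0])
    out["Y"] = norm
    out.attrs.update(df.attrs)
    return out


def aggregate_replicates(df: pd.DataFrame, paper_style: bool = False) -> pd.DataFrame:
    """Per (gene, time) mean and SEM of normalized levels across replicates.

    SEM = sd/sqrt(n) with sd at ddof 1; undefined (NaN) for n = 1. With
    ``paper_style`` the SEM is also suppressed for n < 3, matching the
    reporting convention of showing error bars only for 3+ biological
    replicates.
    """
    if "Y" not in df.columns:
        raise ValueError("run relative_abundance first (no Y column)")
    grouped = df.groupby(["gene", "time"])["Y"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    min_n = 3 if paper_style else 2
    out.loc[out["n"] < min_n, "sem"] = np.nan
    return out.drop(columns="sd")


def _slope_intercept(t: np.ndarray, ln_y: np.ndarray) -> tuple[float, float]:
    t_mean = t.mean()
    var = np.sum((t - t_mean) ** 2)
    slope = np.sum((t - t_mean) * (ln_y - ln_y.mean())) / var
    return slope, ln_y.mean() - slope * t_mean


def fit_decay(times, y, gene: str = "") -> DecayFit:
    """Least-squares line on (t, ln Y); k is the negated slope.

    Requires >= 3 points over >= 2 distinct times and strictly positive Y.
    A non-positive estimated k (rising or flat signal) is allowed but
    flagged via ``DecayFit.rising``; its half-life is infinite.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and levels differ in length")
    if len(t) < 3 or len(np.unique(t)) < 2:
        raise ValueError("need >= 3 points spanning >= 2 distinct times")
    if np.any(y <= 0):
        raise ValueError("all levels must be positive (log scale)")
    slope, intercept = _slope_intercept(t, np.log(y))
    k = -slope
    if k <= 0:
        logger.warning("gene %s: non-decaying fit (k = %.4g)", gene, k)
    half_life = LN2 / k if k > 0 else float("inf")
    return DecayFit(gene=gene, k=k, intercept=intercept, half_life=half_life, n_points=len(t))


def bootstrap_ci(
    times,
    y,
    n_boot: int = 1000,
    seed: int | None = None,
    gene: str = "",
) -> DecayFit:
    """Case-resampling bootstrap of the decay fit, percentile 95% interval.

    Resamples (t, ln Y) pairs with replacement; resamples with fewer than
    2 distinct times are redrawn. The draws are stored on the result so
    fits can later be compared pairwise; the per-time 2.5/97.5% band of
    the fitted line is exported for plotting.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 100:
        logger.warning("n_boot = %d is small; intervals will be unstable", n_boot)
    fit = fit_decay(times, y, gene=gene)
    t = np.asarray(times, dtype=float)
    ln_y = np.log(np.asarray(y, dtype=float))
    rng = np.random.default_rng(seed)
    n = len(t)
    idx = rng.integers(0, n, size=(n_boot, n))
    # redraw degenerate resamples (single distinct time)
    for _ in range(1000):
        degenerate = (t[idx].max(axis=1) - t[idx].min(axis=1)) == 0
        if not degenerate.any():
            break
        idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
    tb = t[idx]
    yb = ln_y[idx]
    tm = tb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    var = np.sum((tb - tm) ** 2, axis=1)
    slopes = np.sum((tb - tm) * (yb - ym), axis=1) / var
    intercepts = ym[:, 0] - slopes * tm[:, 0]
    k_draws = -slopes
    lo, hi = np.quantile(k_draws, [0.025, 0.975])
    grid = np.unique(t)
    lines = intercepts[:, None] + slopes[:, None] * grid[None, :]
    band_lo, band_hi = np.quantile(lines, [0.025, 0.975], axis=0)
    band = pd.DataFrame(
        {
            "time": grid,
            "fit": fit.intercept - fit.k * grid,
            "lo": band_lo,
            "hi": band_hi,
        }
    )
    fit.ci_low, fit.ci_high = float(lo), float(hi)
    fit.n_boot = n_boot
    fit.seed = seed
    fit.k_draws = k_draws
    fit.band = band
    return fit


def compare_decay(fits: dict[str, DecayFit] | list[DecayFit]) -> pd.DataFrame:
    """Pairwise bootstrap comparison of decay constants.

    For every pair, the bootstrap distribution of k_a - k_b (paired over
    the stored draws) gives a percentile 95% CI on the difference; a pair
    is flagged significant when that CI excludes zero. All fits must carry
    stored draws of equal length.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    for f in fits:
        if f.k_draws is None:
            raise ValueError(f"fit for {f.gene!r} lacks stored bootstrap draws")
    n_draws = {len(f.k_draws) for f in fits}
    if len(n_draws) > 1:
        raise ValueError("fits have differing numbers of bootstrap draws")
    rows = []
    for fa, fb in combinations(fits, 2):
        diff = fa.k_draws - fb.k_draws
        lo, hi = np.quantile(diff, [0.025, 0.975])
        rows.append(
            {
                "gene_a": fa.gene,
                "gene_b": fb.gene,
                "delta_k": fa.k - fb.k,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def analyze_timecourse(
    df: pd.DataFrame,
    convention: str = "standard",
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, DecayFit]:
    """Full pipeline: delta-Ct -> t0 normalization -> bootstrap decay fit.

    Fits each gene on all of its replicate points. Per-gene bootstrap
    seeds are spawned deterministically from ``seed``.
    """
    levels = normalize_to_t0(relative_abundance(df, convention))
    fits: dict[str, DecayFit] = {}
    rng = np.random.default_rng(seed)
    for gene in sorted(levels["gene"].unique()):
        sub = levels[levels["gene"] == gene]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fits[gene] = bootstrap_ci(
            sub["time"].to_numpy(), sub["Y"].to_numpy(), n_boot=n_boot, seed=sub_seed, gene=gene
        )
    return fits
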