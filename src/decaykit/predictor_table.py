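"""Assembly of the gene x predictor matrix and response-outlier filtering.

Predictors arrive from heterogeneous per-gene sources (sequence features,
abundance, ribosome density, UTR properties, ...). Most are roughly
log-normal and are log10-transformed before modeling; proportions (GC by
codon position), nTE and folding energy stay on their original scale. The
response — the degradation rate constant, min^-1, approximately normal —
is never transformed, but extreme rates are removed with Tukey fences
(quartiles +/- 1.5 IQR) before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSFORMS",
    "TransformSpec",
    "PredictorTable",
    "IqrFilterResult",
    "apply_transform",
    "assemble",
    "iqr_filter",
]

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log10", "log10_plus1")


@dataclass(frozen=True)
class TransformSpec:
    """Per-predictor transformation: none, log10 or log10(x + 1)."""

    predictor_name: str
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Element-wise transform; out-of-domain values become NaN (counted)."""
    values = np.asarray(values, dtype=float)
    finite = ~np.isnan(values)
    if spec.transform == "none":
        return values.copy()
    if spec.transform == "log10":
        bad = finite & (values <= 0)
        arg = values
    else:  # log10_plus1
        bad = finite & (values <= -1)
        arg = values + 1
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.warning(
            "%s: %d values outside the domain of %s set to missing",
            spec.predictor_name,
            n_bad,
            spec.transform,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, np.log10(np.where(bad, np.nan, arg)))
    return out


@dataclass
class PredictorTable:
    """Gene x predictor matrix with transform metadata and aligned response.

    ``data`` holds the transformed predictor columns (one row per gene in
    the response); ``response`` is the degradation rate constant (min^-1),
    positive where present and never transformed. Missing values are kept:
    complete-case handling happens per fitted model, not at assembly.
    """

    data: pd.DataFrame
    response: pd.Series
    transforms: dict[str, TransformSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.response.index):
            raise ValueError("data and response must share the same gene index")
        for name in self.data.columns:
            self.transforms.setdefault(name, TransformSpec(name, "none"))
        present = self.response.dropna()
        if (present <= 0).any():
            raise ValueError("response rate constants must be positive where present")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    def coverage(self) -> pd.Series:
        """Non-missing count per predictor column."""
        return self.data.notna().sum()

    def subset(self, genes: Sequence) -> "PredictorTable":
        return PredictorTable(
            self.data.loc[genes].copy(), self.response.loc[genes].copy(), dict(self.transforms)
        )

    def with_response(self, response: pd.Series) -> "PredictorTable":
        return PredictorTable(self.data.copy(), response, dict(self.transforms))

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "k_deg", self.response)
        return out


def assemble(
    sources: Iterable[tuple[str, Mapping]],
    transforms: Sequence[TransformSpec],
    response: Mapping,
) -> PredictorTable:
    """Join per-gene value maps into a PredictorTable over the response genes.

    Each source is (predictor_name, gene -> value). Rows are the genes of
    the response; sources covering only part of them contribute missing
    values (per-column coverage is logged, mirroring heterogeneous dataset
    sizes). Transforms are applied here, on original units.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("at least one source is required")
    spec_by_name = {s.predictor_name: s for s in transforms}
    resp = pd.Series(dict(response), dtype=float).sort_index()
    resp.name = "k_deg"
    columns = {}
    for name, mapping in sources:
        if isinstance(mapping, pd.Series):
            series = mapping.astype(float)
        else:
            series = pd.Series(dict(mapping), dtype=float)
        if series.index.has_duplicates:
            dups = series.index[series.index.duplicated()].unique().tolist()
            raise ValueError(f"source {name!r} has duplicate gene_ids: {dups[:5]}")
        aligned = series.reindex(resp.index)
        spec = spec_by_name.get(name, TransformSpec(name, "none"))
        columns[name] = pd.Series(apply_transform(aligned.to_numpy(), spec), index=resp.index)
        logger.info("source %s: %d/%d genes covered", name, aligned.notna().sum(), len(resp))
    data = pd.DataFrame(columns)
    table = PredictorTable(data, resp, {n: spec_by_name.get(n, TransformSpec(n)) for n in data})
    return table


@dataclass
class IqrFilterResult:
    kept: pd.Index
    excluded: pd.Index
    excluded_fraction: float
    lower_fence: float
    upper_fence: float


def iqr_filter(
    response: pd.Series | np.ndarray,
    factor: float = 1.5,
    one_sided_upper: bool = False,
) -> IqrFilterResult:
    """Tukey-fence outlier filter on the response (single pass).

    Fences are [Q1 - factor*IQR, Q3 + factor*IQR] with quartiles by linear
    interpolation (type 7), computed on non-missing values. With
    ``one_sided_upper`` only the upper fence excludes (rate constants are
    bounded below by zero, so some analyses drop only fast-decay outliers).
    """
    series = pd.Series(response).astype(float)
    values = series.dropna()
    if len(values) == 0:
        raise ValueError("response is all-missing")
    if len(values) < 4:
        raise ValueError("need at least 4 non-missing values for quartiles")
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lower = q1 - factor * iqr
    upper = q3 + factor * iqr
    if one_sided_upper:
        out_mask = values > upper
        lower = -np.inf
    else:
        out_mask = (values < lower) | (values > upper)
    excluded = values.index[out_mask]
    kept = values.index[~out_mask]
    frac = len(excluded) / len(values)
    logger.info(
        "IQR filter: %d of %d non-missing rates excluded (%.2f%%)",
        len(excluded),
        len(values),
        100 * frac,
    )
    return IqrFilterResult(kept, excluded, frac, float(lower), float(upper))
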