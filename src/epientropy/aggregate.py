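"""Feature-level aggregation of per-CpG methylation and per-4-mer entropy.

Feature means are unweighted arithmetic means.  A feature's methylation mean
is reported only when at least ``min_cpgs`` CpGs (default 3) are covered
inside it; a 4-mer is assigned to a feature when any of its four positions
falls inside the feature interval (an all-inside mode is available).  For
multi-sample comparisons, features are masked to those summarized in at
least a given fraction of the samples (1.0 = intersection across all
samples; 0.8 accommodates long time-courses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Feature

DEFAULT_MIN_CPGS = 3


@dataclass(frozen=True, slots=True)
class FeatureSummary:
    feature_id: str
    sample_id: str | None
    mean_methylation: float
    mean_entropy: float
    n_cpgs: int
    n_fourmers: int


def aggregate_methylation(
    feature: Feature,
    rates: pd.DataFrame,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    sample_id: str | None = None,
) -> FeatureSummary:
    """Unweighted mean of per-CpG rates inside a feature.

    Missing (NaN) unless at least ``min_cpgs`` CpGs are covered inside the
    feature interval.
    """
    sub = rates[
        (rates["chrom"] == feature.chrom)
        & (rates["pos"] >= feature.start)
        & (rates["pos"] < feature.end)
    ]
    n = len(sub)
    mean = float(sub["rate"].mean()) if n >= min_cpgs else math.nan
    return FeatureSummary(feature.id, sample_id, mean, math.nan, n, 0)


def aggregate_entropy(
    feature: Feature,
    records: pd.DataFrame,
    mode: str = "any",
    sample_id: str | None = None,
) -> FeatureSummary:
    """Unweighted mean of 4-mer entropies assigned to a feature.

    ``any``: a 4-mer belongs to the feature if any of its four CpGs lies
    inside; ``all``: all four must lie inside.  Missing if none assigned.
    """
    mask = _assign_fourmers(feature, records, mode)
    n = int(mask.sum())
    mean = float(records.loc[mask, "entropy"].mean()) if n else math.nan
    return FeatureSummary(feature.id, sample_id, math.nan, mean, 0, n)


def _assign_fourmers(feature: Feature, records: pd.DataFrame, mode: str) -> pd.Series:
    if mode not in ("any", "all"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    on_chrom = records["chrom"] == feature.chrom
    inside = [
        (records[c] >= feature.start) & (records[c] < feature.end)
        for c in ("pos1", "pos2", "pos3", "pos4")
    ]
    combined = inside[0]
    for m in inside[1:]:
        combined = (combined | m) if mode == "any" else (combined & m)
    return on_chrom & combined


def summarize_features(
    features: Sequence[Feature],
    rates: pd.DataFrame | None = None,
    entropy_records: pd.DataFrame | None = None,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    fourmer_mode: str = "any",
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Per-feature summary table combining methylation and entropy means."""
    rows = []
    for feat in features:
        mean_meth, n_cpgs = math.nan, 0
        mean_ent, n_fm = math.nan, 0
        if rates is not None:
            s = aggregate_methylation(feat, rates, min_cpgs)
            mean_meth, n_cpgs = s.mean_methylation, s.n_cpgs
        if entropy_records is not None:
            s = aggregate_entropy(feat, entropy_records, fourmer_mode)
            mean_ent, n_fm = s.mean_entropy, s.n_fourmers
        rows.append(
            {
                "feature_id": feat.id,
                "chrom": feat.chrom,
                "start": feat.start,
                "end": feat.end,
                "sample_id": sample_id,
                "n_cpgs": n_cpgs,
                "n_fourmers": n_fm,
                "mean_methylation": mean_meth,
                "mean_entropy": mean_ent,
            }
        )
    return pd.DataFrame(rows)


def mask_common_features(
    summaries: Mapping[str, pd.DataFrame],
    min_fraction: float = 1.0,
    column: str = "mean_methylation",
) -> dict[str, pd.DataFrame]:
    """Restrict per-sample summaries to features observed in enough samples.

    A feature counts as observed in a sample when its ``column`` value is
    non-missing.  ``min_fraction`` = 1.0 keeps the all-sample intersection;
    0.8 keeps features observed in at least 80% of samples.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_samples = len(summaries)
    present = pd.DataFrame(
        {
            sample: df.set_index("feature_id")[column].notna()
            for sample, df in summaries.items()
        }
    ).fillna(False)
    keep = present.index[present.sum(axis=1) >= min_fraction * n_samples]
    return {
        sample: df[df["feature_id"].isin(keep)].reset_index(drop=True)
        for sample, df in summaries.items()
    }


def reciprocal_overlap_labels(
    tiles: Sequence[Feature],
    cgis: Sequence[Feature],
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Label tiles that overlap a CGI by at least 20% of either interval.

    Used to classify genomic tiles for density/scatter displays: a tile is
    labelled if the overlap covers >= ``min_fraction`` of the tile or of the
    CGI.
    """
    cgi_by_chrom: dict[str, list[Feature]] = {}
    for c in cgis:
        cgi_by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for t in tiles:
        hit = False
        for c in cgi_by_chrom.get(t.chrom, ()):
            ov = min(t.end, c.end) - max(t.start, c.start)
            if ov <= 0:
                continue
            if ov >= min_fraction * t.length or ov >= min_fraction * c.length:
                hit = True
                break
        rows.append({"feature_id": t.id, "overlaps_cgi": hit})
    return pd.DataFrame(rows)
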