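"""Hyper-CGI calling: CpG islands gaining methylation in a contrast.

Two definitions are implemented.

Differential (epiblast vs extra-embryonic ectoderm): a CGI is *hyper* when
the difference of its average methylation (ExE minus epiblast) exceeds 0.1
AND either more than half of the CpGs covered in both conditions differ by
at least 0.1, or the CGI overlaps an externally supplied differentially
methylated region (hyper in ExE, q < 0.05).  CGIs already methylated in
the epiblast (mean >= 0.2) are excluded regardless.  CGI means follow the
feature-aggregation rule (at least 3 covered CpGs per condition).

Knockout gain: a CGI is included when its mean methylation gains at least
0.2 in any knockout relative to wild type — strong absolute gain,
independent of the wild-type level.

DMR calling itself is out of scope here; the DMR criterion consumes a
pre-computed interval track (e.g. metilene output with
``-m 10 -d 0.1 -c 2 -f 1 -M 80 -v 0.7``) supplied as BED with a q-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import DEFAULT_MIN_CPGS
from .io import Feature

logger = logging.getLogger(__name__)

DEFAULT_DIFF_THRESHOLD = 0.1
DEFAULT_CPG_FRACTION = 0.5
DEFAULT_EPI_MAX = 0.2
DEFAULT_GAIN_THRESHOLD = 0.2
DMR_Q_MAX = 0.05


@dataclass(frozen=True, slots=True)
class DMR:
    """A differentially methylated region from an external caller."""

    chrom: str
    start: int
    end: int
    q_value: float
    direction: str = "hyper"  # "hyper" = more methylated in the gaining condition


@dataclass(frozen=True, slots=True)
class HyperCGICall:
    cgi_id: str
    status: str  # hyper | not_hyper | excluded | missing
    mean_diff: float
    frac_cpgs_diff: float
    dmr_overlap: bool
    epiblast_mean: float


def read_dmr_track(path: str | Path) -> list[DMR]:
    """Read a DMR BED: chrom, start, end, q_value[, direction]."""
    dmrs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: need >= 4 fields")
            direction = fields[4] if len(fields) >= 5 else "hyper"
            dmrs.append(
                DMR(fields[0], int(fields[1]), int(fields[2]),
                    float(fields[3]), direction)
            )
    return dmrs


def average_rate_tracks(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-CpG replicate averaging: mean rate across replicates covering a CpG.

    Counts are summed so downstream tools still see total depth; the rate is
    the unweighted mean of replicate rates (replicates averaged per CpG
    first, features averaged after).
    """
    merged = pd.concat(tracks, ignore_index=True)
    grouped = merged.groupby(["chrom", "pos"], as_index=False).agg(
        rate=("rate", "mean"),
        n_meth=("n_meth", "sum"),
        n_total=("n_total", "sum"),
    )
    return grouped.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _cgi_rates(cgi: Feature, rates: pd.DataFrame) -> pd.DataFrame:
    return rates[
        (rates["chrom"] == cgi.chrom)
        & (rates["pos"] >= cgi.start)
        & (rates["pos"] < cgi.end)
    ]


def _overlaps_dmr(cgi: Feature, dmrs: Iterable[DMR]) -> bool:
    for d in dmrs:
        if (
            d.chrom == cgi.chrom
            and d.direction == "hyper"
            and d.q_value < DMR_Q_MAX
            and min(cgi.end, d.end) > max(cgi.start, d.start)
        ):
            return True
    return False


def call_hyper_cgis(
    cgis: Sequence[Feature],
    epi_rates: pd.DataFrame,
    exe_rates: pd.DataFrame,
    dmrs: Sequence[DMR] | None = None,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    cpg_fraction: float = DEFAULT_CPG_FRACTION,
    epi_max: float = DEFAULT_EPI_MAX,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> list[HyperCGICall]:
    """Call differential hyper CGIs from two per-CpG rate tracks.

    Thresholds are taken literally: the CGI-mean difference must be
    strictly greater than ``diff_threshold``; strictly more than
    ``cpg_fraction`` of the CpGs covered in both conditions must differ by
    at least ``diff_threshold``; CGIs with a baseline (epiblast) mean at or
    above ``epi_max`` are excluded.  CGIs with fewer than ``min_cpgs``
    covered CpGs in either condition get status ``missing``.
    """
    calls = []
    for cgi in cgis:
        epi = _cgi_rates(cgi, epi_rates)
        exe = _cgi_rates(cgi, exe_rates)
        if len(epi) < min_cpgs or len(exe) < min_cpgs:
            logger.info("CGI %s: insufficient CpG coverage, status missing", cgi.id)
            calls.append(
                HyperCGICall(cgi.id, "missing", math.nan, math.nan, False, math.nan)
            )
            continue
        epi_mean = float(epi["rate"].mean())
        exe_mean = float(exe["rate"].mean())
        mean_diff = exe_mean - epi_mean

        shared = pd.merge(
            epi[["pos", "rate"]],
            exe[["pos", "rate"]],
            on="pos",
            suffixes=("_epi", "_exe"),
        )
        if len(shared):
            per_cpg_diff = shared["rate_exe"] - shared["rate_epi"]
            frac = float((per_cpg_diff >= diff_threshold).mean())
        else:
            frac = math.nan
        dmr_hit = _overlaps_dmr(cgi, dmrs) if dmrs else False

        if epi_mean >= epi_max:
            status = "excluded"
        elif mean_diff > diff_threshold and (
            (not math.isnan(frac) and frac > cpg_fraction) or dmr_hit
        ):
            status = "hyper"
        else:
            status = "not_hyper"
        calls.append(
            HyperCGICall(cgi.id, status, mean_diff, frac, dmr_hit, epi_mean)
        )
    return calls


def call_prc_hyper_cgis(
    wt_means: Mapping[str, float] | pd.Series,
    ko_means: Mapping[str, Mapping[str, float] | pd.Series],
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
) -> set[str]:
    """CGIs gaining >= ``gain_threshold`` mean methylation in any knockout.

    ``wt_means`` maps CGI id to the wild-type CGI mean; ``ko_means`` maps
    knockout name to such a mapping.  CGIs without a wild-type mean are
    skipped (logged); a CGI only needs a mean in one knockout to qualify.
    """
    wt = pd.Series(wt_means, dtype=float)
    included: set[str] = set()
    for cgi_id, wt_mean in wt.items():
        if math.isnan(wt_mean):
            logger.info("CGI %s: wild-type mean missing, skipped", cgi_id)
            continue
        for ko_name, means in ko_means.items():
            ko = pd.Series(means, dtype=float)
            if cgi_id not in ko.index or math.isnan(ko[cgi_id]):
                continue
            if ko[cgi_id] - wt_mean >= gain_threshold:
                included.add(str(cgi_id))
                break
    return included


def calls_to_frame(calls: Sequence[HyperCGICall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cgi_id": c.cgi_id,
                "status": c.status,
                "mean_diff": c.mean_diff,
                "frac_cpgs_diff": c.frac_cpgs_diff,
                "dmr_overlap": c.dmr_overlap,
                "epiblast_mean": c.epiblast_mean,
            }
            for c in calls
        ]
    )
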