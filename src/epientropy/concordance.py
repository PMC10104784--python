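"""Phased CGI-pair coordination from long reads.

Long reads that fully span two hypermethylating CpG islands phase their
methylation states onto the same molecule.  For each such pair, every
shared read r contributes its per-read mean methylation over each island,
(x_r, y_r).  A read is *concordant* when both means fall on the same side
of their island's population median (computed from all spanning reads of
that island, not only the pair's shared reads):

    concordant(r)  iff  (x_r > med_x and y_r > med_y)
                     or (x_r <= med_x and y_r <= med_y)

Ties at the median count to the low side.  The observed concordant-read
fraction is compared with a shuffle null: the y-values are permuted across
reads (default 100 times), the fraction recomputed against the same
medians, and the mean across permutations reported.  For independent
islands the null expectation is (n_hx*n_hy + n_lx*n_ly) / n^2, about 0.5
for balanced splits; read-level coordination pushes the observed fraction
above it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Feature, ReadProfile

DEFAULT_MIN_READS = 10
DEFAULT_N_SHUFFLES = 100


@dataclass
class CGIPair:
    """Two hyper CGIs phased on shared long reads."""

    cgi_a: Feature
    cgi_b: Feature
    read_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    median_x: float
    median_y: float
    concordance: float
    null_mean: float

    @property
    def n_reads(self) -> int:
        return int(self.x.size)

    @property
    def delta(self) -> float:
        return self.concordance - self.null_mean

    @property
    def distance_bp(self) -> int:
        first, second = sorted(
            (self.cgi_a, self.cgi_b), key=lambda f: f.start
        )
        return max(0, second.start - first.end)


def select_spanning_reads(
    reads: Sequence[ReadProfile],
    hyper_cgis: Sequence[Feature],
    min_reads_per_cgi: int = DEFAULT_MIN_READS,
) -> dict[str, list[ReadProfile]]:
    """Map each retained hyper CGI to the reads that completely span it.

    A read spans a CGI iff its aligned interval fully contains the CGI
    interval.  Reads spanning fewer than two complete hyper CGIs are
    dropped first; CGIs left with fewer than ``min_reads_per_cgi`` spanning
    reads are then discarded.
    """
    per_read: dict[str, list[str]] = {}
    spanning: dict[str, list[ReadProfile]] = {c.id: [] for c in hyper_cgis}
    cgi_by_id = {c.id: c for c in hyper_cgis}
    for read in reads:
        hit = [
            c.id
            for c in hyper_cgis
            if c.chrom == read.chrom and read.spans(c.start, c.end)
        ]
        if len(hit) >= 2:
            per_read[read.read_id] = hit
            for cid in hit:
                spanning[cid].append(read)
    return {
        cid: rds
        for cid, rds in spanning.items()
        if len(rds) >= min_reads_per_cgi and cid in cgi_by_id
    }


def per_read_cgi_mean(
    read: ReadProfile, cgi: Feature, min_calls: int = 1
) -> float:
    """Mean of a read's binary calls at CpGs inside the CGI (NaN if too few)."""
    inside = (read.positions >= cgi.start) & (read.positions < cgi.end)
    n = int(inside.sum())
    if n < min_calls:
        return float("nan")
    return float(read.states[inside].mean())


def concordance_fraction(
    pair_values: Sequence[tuple[float, float]] | np.ndarray,
    median_x: float,
    median_y: float,
) -> float:
    """Fraction of reads on the same side of both island medians."""
    arr = np.asarray(pair_values, dtype=np.float64)
    x, y = arr[:, 0], arr[:, 1]
    high = (x > median_x) & (y > median_y)
    low = (x <= median_x) & (y <= median_y)
    return float((high | low).mean())


def exact_null_mean(
    pair_values: Sequence[tuple[float, float]] | np.ndarray,
    median_x: float,
    median_y: float,
) -> float:
    """Analytic mean concordance over all permutations of the y-values.

    Equals (n_hx*n_hy + n_lx*n_ly) / n^2 where n_h*/n_l* count reads above
    / at-or-below each median.
    """
    arr = np.asarray(pair_values, dtype=np.float64)
    n = arr.shape[0]
    n_hx = int((arr[:, 0] > median_x).sum())
    n_hy = int((arr[:, 1] > median_y).sum())
    return (n_hx * n_hy + (n - n_hx) * (n - n_hy)) / n**2


def shuffle_null(
    pair_values: Sequence[tuple[float, float]] | np.ndarray,
    median_x: float,
    median_y: float,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Mean concordance after permuting y across reads ``n_shuffles`` times.

    Medians are held fixed at their observed values.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.asarray(pair_values, dtype=np.float64)
    x, y = arr[:, 0], arr[:, 1]
    x_high = x > median_x
    fracs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_perm = rng.permutation(y)
        y_high = y_perm > median_y
        fracs[i] = ((x_high & y_high) | (~x_high & ~y_high)).mean()
    return float(fracs.mean())


def cgi_pair_table(
    reads: Sequence[ReadProfile],
    hyper_cgis: Sequence[Feature],
    min_reads_per_cgi: int = DEFAULT_MIN_READS,
    min_shared_reads: int = DEFAULT_MIN_READS,
    min_calls: int = 1,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Full pair analysis: concordance and shuffle null for every CGI pair.

    Pairs are all unordered pairs of retained hyper CGIs on one chromosome
    sharing at least ``min_shared_reads`` spanning reads; no maximum
    genomic distance is imposed.  Medians are taken per CGI over all its
    spanning reads with at least ``min_calls`` calls inside the island.
    """
    spanning = select_spanning_reads(reads, hyper_cgis, min_reads_per_cgi)
    cgi_by_id = {c.id: c for c in hyper_cgis}

    # unphased per-read means and medians, per retained CGI
    means: dict[str, dict[str, float]] = {}
    medians: dict[str, float] = {}
    for cid, rds in spanning.items():
        cgi = cgi_by_id[cid]
        vals = {}
        for r in rds:
            m = per_read_cgi_mean(r, cgi, min_calls)
            if not np.isnan(m):
                vals[r.read_id] = m
        if len(vals) < min_reads_per_cgi:
            continue
        means[cid] = vals
        medians[cid] = float(np.median(list(vals.values())))

    rows = []
    kept = sorted(means, key=lambda cid: (cgi_by_id[cid].chrom, cgi_by_id[cid].start))
    for cid_a, cid_b in itertools.combinations(kept, 2):
        a, b = cgi_by_id[cid_a], cgi_by_id[cid_b]
        if a.chrom != b.chrom:
            continue
        shared = sorted(set(means[cid_a]) & set(means[cid_b]))
        if len(shared) < min_shared_reads:
            continue
        values = np.array(
            [(means[cid_a][rid], means[cid_b][rid]) for rid in shared]
        )
        conc = concordance_fraction(values, medians[cid_a], medians[cid_b])
        rng = np.random.default_rng(
            [seed, zlib.crc32(f"{cid_a}|{cid_b}".encode())]
        )
        null = shuffle_null(
            values, medians[cid_a], medians[cid_b], n_shuffles, rng
        )
        pair = CGIPair(
            a, b, shared, values[:, 0], values[:, 1],
            medians[cid_a], medians[cid_b], conc, null,
        )
        rows.append(
            {
                "cgi_a": cid_a,
                "cgi_b": cid_b,
                "chrom": a.chrom,
                "distance_bp": pair.distance_bp,
                "n_reads": pair.n_reads,
                "concordance": conc,
                "null_mean": null,
                "delta": pair.delta,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cgi_a", "cgi_b", "chrom", "distance_bp", "n_reads",
            "concordance", "null_mean", "delta",
        ],
    )
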