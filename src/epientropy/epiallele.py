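"""Epiallele counting and methylation entropy over 4-mers of consecutive CpGs.

An *epiallele* is one of the 16 possible binary methylation configurations
of four consecutive CpGs observed on a single read.  The entropy of a 4-mer
is the Shannon entropy (in bits) of its epiallele frequency distribution,
normalized by 4 so it lies in [0, 1]:

    H = -(1/4) * sum_i (c_i / N) * log2(c_i / N)

with N the number of reads spanning all four CpGs.  H = 0 when every read
carries the same configuration; H = 1 when all 16 configurations occur at
equal frequency.  Homogeneous populations (clonal inheritance of a fixed
pattern) and stochastic per-molecule methylation are thereby separable even
at identical mean methylation.

Epiallele index convention: configuration (b1, b2, b3, b4) with b = 1 for
methylated maps to index 8*b1 + 4*b2 + 2*b3 + b4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ReadProfile

N_EPIALLELES = 16
FOURMER_SIZE = 4

#: Number of methylated CpGs in each epiallele configuration (popcount 0..15).
POPCOUNT = np.array([bin(i).count("1") for i in range(N_EPIALLELES)], dtype=np.int64)

#: Bit weights mapping a (b1, b2, b3, b4) state vector to its epiallele index.
BIT_WEIGHTS = np.array([8, 4, 2, 1], dtype=np.int64)

DEFAULT_MIN_COVERAGE = 10
DEFAULT_MAX_COVERAGE = 150


@dataclass(frozen=True, slots=True)
class FourMer:
    """A window of four consecutive CpGs in reference order."""

    chrom: str
    positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.positions) != FOURMER_SIZE:
            raise ValueError("a 4-mer needs exactly four CpG positions")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("4-mer positions must be strictly increasing")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.positions[0]}-{self.positions[3]}"


@dataclass(slots=True)
class EpialleleCounts:
    """Counts of the 16 epiallele configurations at one 4-mer."""

    fourmer_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_EPIALLELES,):
            raise ValueError("counts must be a length-16 vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True, slots=True)
class EntropyRecord:
    fourmer_id: str
    entropy: float
    mean_methylation: float
    coverage: int


# ---------------------------------------------------------------------------
# 4-mer enumeration


def enumerate_fourmers(
    cpg_positions: Mapping[str, Sequence[int]] | Sequence[int],
    mode: str = "sliding",
    chrom: str = "chr1",
) -> list[FourMer]:
    """Enumerate 4-mers of consecutive CpGs per chromosome.

    ``sliding`` advances the window by one CpG (dense, overlapping 4-mers);
    ``disjoint`` advances by four.  4-mers never span chromosomes.
    """
    if mode not in ("sliding", "disjoint"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(cpg_positions, Mapping):
        cpg_positions = {chrom: cpg_positions}
    step = 1 if mode == "sliding" else FOURMER_SIZE
    fourmers: list[FourMer] = []
    for chrom_name in cpg_positions:
        pos = np.asarray(cpg_positions[chrom_name], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom_name}: CpG positions must be strictly increasing")
        for i in range(0, pos.size - FOURMER_SIZE + 1, step):
            fourmers.append(FourMer(chrom_name, tuple(pos[i : i + FOURMER_SIZE])))
    return fourmers


# ---------------------------------------------------------------------------
# counting


def count_epialleles(reads: Iterable[ReadProfile], fourmer: FourMer) -> EpialleleCounts:
    """Count epialleles at one 4-mer from reads spanning all four CpGs.

    A read contributes one count iff it has a call at every one of the four
    positions; partial overlaps contribute nothing.
    """
    counts = np.zeros(N_EPIALLELES, dtype=np.int64)
    target = np.asarray(fourmer.positions, dtype=np.int64)
    for read in reads:
        if read.chrom != fourmer.chrom:
            continue
        idx = np.searchsorted(read.positions, target)
        if (idx >= read.positions.size).any():
            continue
        if not (read.positions[idx] == target).all():
            continue
        code = int(BIT_WEIGHTS @ read.states[idx].astype(np.int64))
        counts[code] += 1
    return EpialleleCounts(fourmer.id, counts)


def epiallele_count_table(
    reads: Sequence[ReadProfile], fourmers: Sequence[FourMer]
) -> pd.DataFrame:
    """Vectorized epiallele counting over many 4-mers.

    Returns one row per 4-mer with columns chrom, pos1..pos4, the 16
    epiallele counts e0..e15 and the coverage.
    """
    by_chrom: dict[str, list[FourMer]] = {}
    for fm in fourmers:
        by_chrom.setdefault(fm.chrom, []).append(fm)

    rows = []
    for chrom, fms in by_chrom.items():
        chrom_reads = [r for r in reads if r.chrom == chrom]
        # union of CpG positions touched by any read or 4-mer on this chrom
        all_pos = np.unique(
            np.concatenate(
                [r.positions for r in chrom_reads]
                + [np.asarray(fm.positions) for fm in fms]
            )
        )
        # reads x positions state matrix, -1 = no call
        mat = np.full((len(chrom_reads), all_pos.size), -1, dtype=np.int8)
        for i, r in enumerate(chrom_reads):
            mat[i, np.searchsorted(all_pos, r.positions)] = r.states
        for fm in fms:
            cols = np.searchsorted(all_pos, np.asarray(fm.positions))
            sub = mat[:, cols]
            full = (sub >= 0).all(axis=1)
            counts = np.zeros(N_EPIALLELES, dtype=np.int64)
            if full.any():
                codes = sub[full].astype(np.int64) @ BIT_WEIGHTS
                counts = np.bincount(codes, minlength=N_EPIALLELES).astype(np.int64)
            rows.append(
                {
                    "fourmer_id": fm.id,
                    "chrom": chrom,
                    "pos1": fm.positions[0],
                    "pos2": fm.positions[1],
                    "pos3": fm.positions[2],
                    "pos4": fm.positions[3],
                    **{f"e{i}": counts[i] for i in range(N_EPIALLELES)},
                    "coverage": int(counts.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# entropy and mean methylation

COUNT_COLUMNS = [f"e{i}" for i in range(N_EPIALLELES)]


def entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy (bits / 4) of epiallele count vectors.

    Accepts an array of shape (..., 16); 0 * log 0 is taken as 0.  Rows with
    zero coverage yield NaN.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum(axis=-1, keepdims=True)
    p = np.divide(counts, total, out=np.zeros_like(counts), where=total > 0)
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    h = -(p * logp).sum(axis=-1) / FOURMER_SIZE + 0.0
    return np.where(total[..., 0] > 0, h, np.nan)


def methylation_from_counts(counts: np.ndarray) -> np.ndarray:
    """Fraction of methylated calls among the 4*N calls of a count vector."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum(axis=-1)
    meth = counts @ POPCOUNT.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = meth / (FOURMER_SIZE * total)
    return np.where(total > 0, m, np.nan)


def _as_count_vector(counts: EpialleleCounts | np.ndarray) -> np.ndarray:
    if isinstance(counts, EpialleleCounts):
        return counts.counts
    return np.asarray(counts)


def entropy(counts: EpialleleCounts | np.ndarray) -> float:
    """Entropy of a single 4-mer's epiallele counts (NaN at zero coverage)."""
    return float(entropy_from_counts(_as_count_vector(counts)))


def fourmer_methylation(counts: EpialleleCounts | np.ndarray) -> float:
    """Mean methylation of a single 4-mer's epiallele counts."""
    return float(methylation_from_counts(_as_count_vector(counts)))


def entropy_table(
    reads: Sequence[ReadProfile],
    fourmers: Sequence[FourMer],
    min_cov: int = DEFAULT_MIN_COVERAGE,
    max_cov: int = DEFAULT_MAX_COVERAGE,
) -> pd.DataFrame:
    """Per-4-mer entropy and mean methylation under the coverage window.

    Only 4-mers with min_cov <= coverage <= max_cov appear in the output;
    under- and over-covered 4-mers are absent, not zero.
    """
    if min_cov > max_cov:
        raise ValueError(f"min_cov {min_cov} exceeds max_cov {max_cov}")
    table = epiallele_count_table(reads, fourmers)
    if table.empty:
        return pd.DataFrame(
            columns=[
                "fourmer_id", "chrom", "pos1", "pos2", "pos3", "pos4",
                "coverage", "entropy", "mean_methylation",
            ]
        )
    keep = (table["coverage"] >= min_cov) & (table["coverage"] <= max_cov)
    table = table.loc[keep].reset_index(drop=True)
    counts = table[COUNT_COLUMNS].to_numpy(dtype=np.int64)
    table["entropy"] = entropy_from_counts(counts)
    table["mean_methylation"] = methylation_from_counts(counts)
    return table[
        [
            "fourmer_id", "chrom", "pos1", "pos2", "pos3", "pos4",
            "coverage", "entropy", "mean_methylation",
        ]
    ]


def write_entropy_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_entropy_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
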