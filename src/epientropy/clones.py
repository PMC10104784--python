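"""Single-cell-sorted clone analysis: in-silico bulk reconstruction.

The test for dynamic vs static methylation inheritance: if intermediate
methylation arises from rapid stochastic turnover, every clonal line
re-equilibrates to the entropy of the parental population; if patterns are
inherited, each clone is near-homogeneous (low entropy) while the pool of
clones remains diverse (high entropy).

The in-silico bulk is built per 4-mer by summing the epiallele counts of
all clones of a line and repeatedly subsampling (default 100 rounds) at the
clones' average coverage; each round's entropy and mean methylation are
computed and their means across rounds reported as the bulk value.
Subsampling is multinomial on the pooled epiallele proportions (i.e. with
replacement), which keeps rounds i.i.d. and is well defined when the target
coverage exceeds any single clone's.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epiallele import (
    COUNT_COLUMNS,
    N_EPIALLELES,
    entropy_from_counts,
    methylation_from_counts,
)

DEFAULT_N_ROUNDS = 100


@dataclass
class CloneSet:
    """Per-clone epiallele count tables aligned on a shared 4-mer universe.

    ``counts`` has shape (n_clones, n_fourmers, 16); clones absent at a
    4-mer carry all-zero counts there.
    """

    clone_ids: list[str]
    fourmer_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (len(self.clone_ids), len(self.fourmer_ids), N_EPIALLELES)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if (self.counts < 0).any():
            raise ValueError("epiallele counts must be non-negative")

    @classmethod
    def from_tables(cls, tables: Mapping[str, pd.DataFrame]) -> "CloneSet":
        """Build from per-clone count tables (epiallele_count_table dialect).

        The 4-mer universe is the union across clones; missing 4-mers get
        zero counts.
        """
        clone_ids = list(tables)
        universe: list[str] = []
        seen = set()
        for df in tables.values():
            for fid in df["fourmer_id"]:
                if fid not in seen:
                    seen.add(fid)
                    universe.append(fid)
        index = {fid: i for i, fid in enumerate(universe)}
        counts = np.zeros((len(clone_ids), len(universe), N_EPIALLELES), dtype=np.int64)
        for ci, clone in enumerate(clone_ids):
            df = tables[clone]
            rows = df["fourmer_id"].map(index).to_numpy()
            counts[ci, rows, :] = df[COUNT_COLUMNS].to_numpy(dtype=np.int64)
        return cls(clone_ids, universe, counts)

    @property
    def coverage(self) -> np.ndarray:
        """Per-clone, per-4-mer coverage, shape (n_clones, n_fourmers)."""
        return self.counts.sum(axis=2)

    def _fourmer_index(self, fourmer_id: str) -> int:
        try:
            return self.fourmer_ids.index(fourmer_id)
        except ValueError:
            raise KeyError(f"unknown 4-mer {fourmer_id!r}") from None


def pool_epialleles(clones: CloneSet, fourmer_id: str | None = None) -> np.ndarray:
    """Elementwise sum of epiallele counts across clones.

    With a ``fourmer_id``, returns that 4-mer's pooled length-16 vector;
    otherwise the full (n_fourmers, 16) pooled matrix.
    """
    pooled = clones.counts.sum(axis=0)
    if fourmer_id is None:
        return pooled
    return pooled[clones._fourmer_index(fourmer_id)]


def _fourmer_rng(seed: int, fourmer_id: str) -> np.random.Generator:
    # Deterministic per-4-mer substream: evaluation order and parallel
    # chunking cannot change the draws.
    return np.random.default_rng([seed, zlib.crc32(fourmer_id.encode())])


def insilico_bulk(
    clones: CloneSet,
    n_rounds: int = DEFAULT_N_ROUNDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruct a pseudo-bulk from clone epiallele counts.

    Per 4-mer: pool counts over clones; set the sampling depth c to the
    average per-clone coverage (half-to-even rounding); draw ``n_rounds``
    multinomial samples of size c from the pooled proportions; report the
    mean entropy and mean methylation across rounds.  4-mers whose rounded
    average coverage is zero are skipped.
    """
    pooled = clones.counts.sum(axis=0)
    avg_cov = clones.coverage.mean(axis=0)
    rows = []
    for j, fid in enumerate(clones.fourmer_ids):
        c = int(np.round(avg_cov[j]))
        total = pooled[j].sum()
        if c == 0 or total == 0:
            continue
        rng = _fourmer_rng(seed, fid)
        p = pooled[j] / total
        draws = rng.multinomial(c, p, size=n_rounds)
        rows.append(
            {
                "fourmer_id": fid,
                "bulk_entropy": float(np.mean(entropy_from_counts(draws))),
                "bulk_methylation": float(np.mean(methylation_from_counts(draws))),
                "n_rounds": n_rounds,
                "sampled_coverage": c,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fourmer_id", "bulk_entropy", "bulk_methylation",
            "n_rounds", "sampled_coverage",
        ],
    )


def clone_bulk_contrast(
    clones: CloneSet,
    bulk: pd.DataFrame,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Tidy per-(4-mer, clone) table of clone entropy next to the bulk value.

    No verdict is computed; the contrast table itself is the deliverable.
    Clones below ``min_cov`` coverage at a 4-mer are reported with missing
    entropy.
    """
    bulk_idx = bulk.set_index("fourmer_id")
    cov = clones.coverage
    ent = entropy_from_counts(clones.counts)
    meth = methylation_from_counts(clones.counts)
    rows = []
    for j, fid in enumerate(clones.fourmer_ids):
        if fid not in bulk_idx.index:
            continue
        b = bulk_idx.loc[fid]
        for ci, clone in enumerate(clones.clone_ids):
            ok = cov[ci, j] >= min_cov
            rows.append(
                {
                    "fourmer_id": fid,
                    "clone_id": clone,
                    "clone_coverage": int(cov[ci, j]),
                    "clone_entropy": float(ent[ci, j]) if ok else np.nan,
                    "clone_methylation": float(meth[ci, j]) if ok else np.nan,
                    "bulk_entropy": float(b["bulk_entropy"]),
                    "bulk_methylation": float(b["bulk_methylation"]),
                }
            )
    return pd.DataFrame(rows)
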