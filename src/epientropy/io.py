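"""Readers and writers for read-level methylation calls, per-CpG rates and
genomic features.

All coordinates are 0-based, half-open, BED-style.  A CpG is identified by
the reference position of its C on the plus strand; calls reported on the
minus strand are destranded to ``pos - 1`` on input so that the two strands
of one CpG collapse onto a single coordinate.

Three text dialects are supported:

* methylation-call TSV — columns ``read_id  chrom  pos  strand  state
  likelihood`` with a ``#``-prefixed header; the likelihood column holds a
  (possibly signed) log-likelihood ratio or ``.`` when the caller provides
  none (bisulfite-derived tables).
* per-CpG rate TSV — bedGraph-like ``chrom  start  end  rate  n_meth
  n_total``.
* BED3/BED6 for features and a UCSC ``.chrom.sizes`` two-column TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default minimum absolute call log-likelihood for nanopore-style calls.
DEFAULT_MIN_ABS_LIKELIHOOD = 2.5

CALL_COLUMNS = ("read_id", "chrom", "pos", "strand", "state", "likelihood")
RATE_COLUMNS = ("chrom", "start", "end", "rate", "n_meth", "n_total")


@dataclass(frozen=True, slots=True)
class MethCall:
    """A single per-read, per-CpG methylation call.

    ``pos`` is the plus-strand C coordinate of the CpG.  ``likelihood`` is
    the absolute log-likelihood of the call, or ``None`` for dialects that
    carry no per-call confidence (bisulfite read extraction).
    """

    read_id: str
    chrom: str
    pos: int
    state: int
    likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative CpG position {self.pos}")
        if self.state not in (0, 1):
            raise ValueError(f"state must be 0 or 1, got {self.state!r}")
        if self.likelihood is not None and self.likelihood < 0:
            raise ValueError("stored likelihood must be non-negative")


@dataclass(slots=True)
class ReadProfile:
    """One read's ordered per-CpG binary methylation states.

    ``positions``/``states`` are parallel arrays sorted by position.  The
    span ``[start, end)`` is the read's aligned interval when known;
    profiles assembled from a bare call stream use the outermost calls as a
    conservative span.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    positions: np.ndarray
    states: np.ndarray
    flagged: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.positions.size != self.states.size:
            raise ValueError("positions and states differ in length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions.size and (
            self.positions[0] < self.start or self.positions[-1] >= self.end
        ):
            raise ValueError("call positions outside read span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def calls(self) -> list[tuple[int, int]]:
        return list(zip(self.positions.tolist(), self.states.tolist()))

    @property
    def n_calls(self) -> int:
        return int(self.positions.size)

    def spans(self, start: int, end: int) -> bool:
        """True if the read's aligned interval fully contains [start, end)."""
        return self.start <= start and self.end >= end


@dataclass(frozen=True, slots=True)
class CpGRate:
    """Aggregate methylation at one CpG: counts and the derived rate."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int
    rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError(
                f"counts out of order: n_meth={self.n_meth}, n_total={self.n_total}"
            )
        if self.n_total == 0:
            raise ValueError("n_total must be positive (rate undefined)")


@dataclass(frozen=True, slots=True)
class Feature:
    """A genomic interval with a class label (cgi, shore, shelf, tile, custom).

    Derived features (shores/shelves) record their parent CGI in ``parent``.
    """

    id: str
    chrom: str
    start: int
    end: int
    feature_class: str = "custom"
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval for {self.id}: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# methylation-call TSV


def read_meth_calls(
    path: str | Path,
    min_abs_likelihood: float = DEFAULT_MIN_ABS_LIKELIHOOD,
) -> Iterator[MethCall]:
    """Stream methylation calls from a TSV, applying the likelihood filter.

    Calls whose absolute log-likelihood is below ``min_abs_likelihood`` are
    dropped; calls without a likelihood (``.``) are kept, which lets
    bisulfite-derived tables bypass the filter.  Minus-strand positions are
    mapped to the plus-strand C coordinate (``pos - 1``) before emission.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 or 6 tab-separated "
                    f"fields, got {len(fields)}"
                )
            read_id, chrom, pos_s, strand, state_s = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be '+' or '-', "
                    f"got {strand!r}"
                )
            if state_s not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: state must be 0 or 1, got {state_s!r}"
                )
            likelihood: float | None = None
            if len(fields) == 6 and fields[5] not in (".", ""):
                try:
                    likelihood = abs(float(fields[5]))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: bad likelihood {fields[5]!r}"
                    ) from None
            if likelihood is not None and likelihood < min_abs_likelihood:
                continue
            if strand == "-":
                pos -= 1
            yield MethCall(read_id, chrom, pos, int(state_s), likelihood)


def write_meth_calls(calls: Iterable[MethCall], path: str | Path) -> None:
    """Write calls in the methylation-call TSV dialect (plus strand only)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            lik = "." if c.likelihood is None else repr(float(c.likelihood))
            fh.write(f"{c.read_id}\t{c.chrom}\t{c.pos}\t+\t{c.state}\t{lik}\n")


def assemble_reads(calls: Iterable[MethCall]) -> list[ReadProfile]:
    """Group a call stream into per-read profiles.

    Duplicate calls at the same position within a read are collapsed when
    they agree; when they conflict the position is dropped from that read
    and the profile is flagged — ambiguity must not fabricate an epiallele.
    """
    grouped: dict[tuple[str, str], dict[int, int]] = {}
    conflicts: dict[tuple[str, str], set[int]] = {}
    order: list[tuple[str, str]] = []
    for c in calls:
        key = (c.read_id, c.chrom)
        if key not in grouped:
            grouped[key] = {}
            conflicts[key] = set()
            order.append(key)
        states = grouped[key]
        if c.pos in states and states[c.pos] != c.state:
            conflicts[key].add(c.pos)
        else:
            states[c.pos] = c.state

    profiles = []
    for key in order:
        read_id, chrom = key
        states = grouped[key]
        bad = conflicts[key]
        if bad:
            logger.warning(
                "read %s (%s): dropping %d position(s) with conflicting "
                "duplicate calls", read_id, chrom, len(bad)
            )
            for pos in bad:
                states.pop(pos, None)
        if not states:
            continue
        positions = np.array(sorted(states), dtype=np.int64)
        st = np.array([states[p] for p in positions], dtype=np.int8)
        profiles.append(
            ReadProfile(
                read_id=read_id,
                chrom=chrom,
                start=int(positions[0]),
                end=int(positions[-1]) + 1,
                positions=positions,
                states=st,
                flagged=bool(bad),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# per-CpG rate TSV

#: Tolerance for consistency between the rate column and n_meth/n_total.
RATE_TOLERANCE = 1e-6


def read_cpg_rates(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph-like per-CpG rate table.

    Returns a DataFrame with columns chrom, pos, rate, n_meth, n_total
    (``pos`` is the interval start; intervals are single CpGs).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=list(RATE_COLUMNS),
        dtype={
            "chrom": str,
            "start": np.int64,
            "end": np.int64,
            "rate": np.float64,
            "n_meth": np.int64,
            "n_total": np.int64,
        },
    )
    if (df["n_total"] <= 0).any():
        raise ValueError("n_total must be positive for every record")
    if (df["n_meth"] > df["n_total"]).any() or (df["n_meth"] < 0).any():
        bad = df.index[(df["n_meth"] > df["n_total"]) | (df["n_meth"] < 0)][0]
        raise ValueError(f"record {bad}: n_meth outside [0, n_total]")
    implied = df["n_meth"] / df["n_total"]
    if (np.abs(implied - df["rate"]) > RATE_TOLERANCE).any():
        bad = df.index[np.abs(implied - df["rate"]) > RATE_TOLERANCE][0]
        raise ValueError(
            f"record {bad}: rate {df['rate'][bad]} inconsistent with counts "
            f"{df['n_meth'][bad]}/{df['n_total'][bad]}"
        )
    out = df.rename(columns={"start": "pos"}).drop(columns=["end"])
    return out[["chrom", "pos", "rate", "n_meth", "n_total"]]


def write_cpg_rates(rates: pd.DataFrame | Iterable[CpGRate], path: str | Path) -> None:
    """Write per-CpG rates; round-trips bit-exactly through read_cpg_rates."""
    if not isinstance(rates, pd.DataFrame):
        rates = pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "rate": r.rate,
                    "n_meth": r.n_meth,
                    "n_total": r.n_total,
                }
                for r in rates
            ]
        )
    with open(path, "w") as fh:
        for row in rates.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.rate!r}\t"
                f"{row.n_meth}\t{row.n_total}\n"
            )


# ---------------------------------------------------------------------------
# features: BED, tiles, shores/shelves


def read_bed(path: str | Path, feature_class: str = "custom") -> list[Feature]:
    """Read BED3+ features, sorted by (chrom, start); ids from column 4 or
    synthesized from coordinates."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = (
                fields[3]
                if len(fields) >= 4 and fields[3] not in (".", "")
                else f"{chrom}:{start}-{end}"
            )
            feats.append(Feature(name, chrom, start, end, feature_class))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return feats


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def make_tiles(
    chrom_sizes: Mapping[str, int], width: int = 1000, step: int = 1000
) -> list[Feature]:
    """Tile each chromosome with fixed-width windows (final partial tile kept).

    ``step == width`` gives the standard non-overlapping 1 kb segmentation.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    tiles: list[Feature] = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, step):
            end = min(start + width, length)
            if end <= start:
                break
            tiles.append(
                Feature(f"{chrom}:{start}-{end}", chrom, start, end, "tile")
            )
    return tiles


def derive_shores_shelves(
    cgis: Sequence[Feature],
    chrom_sizes: Mapping[str, int] | None = None,
    flank: int = 2000,
) -> list[Feature]:
    """Derive CGI shores (2 kb flanks) and shelves (2 kb beyond the shores).

    Intervals are truncated at chromosome bounds; overlaps between derived
    features of neighbouring CGIs are intentionally kept as-is.
    """
    out: list[Feature] = []

    def clip(start: int, end: int, chrom: str) -> tuple[int, int]:
        start = max(start, 0)
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        return start, end

    for cgi in cgis:
        pieces = [
            ("shore", cgi.start - flank, cgi.start, "L"),
            ("shore", cgi.end, cgi.end + flank, "R"),
            ("shelf", cgi.start - 2 * flank, cgi.start - flank, "L"),
            ("shelf", cgi.end + flank, cgi.end + 2 * flank, "R"),
        ]
        for cls, start, end, side in pieces:
            start, end = clip(start, end, cgi.chrom)
            if start >= end:
                continue
            out.append(
                Feature(
                    f"{cgi.id}_{cls}_{side}",
                    cgi.chrom,
                    start,
                    end,
                    cls,
                    parent=cgi.id,
                )
            )
    return out
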