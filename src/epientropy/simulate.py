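"""Synthetic read-level methylation data with known ground truth.

The generator emulates the methylation regimes the analysis is designed to
distinguish, so every stage of the package is testable without sequencing
data:

* bimodal somatic-like methylomes — CpGs near 0 or near 1, homogeneous
  across molecules (low epiallele entropy);
* disordered intermediate methylomes — every call an independent
  Bernoulli(m) draw per molecule, i.e. stochastic per-CpG states whose
  entropy approaches 1 at m = 0.5 (allelic heterogeneity);
* clonal populations — *dynamic* clones re-equilibrate to the parental
  distribution (every clone re-draws calls i.i.d.), whereas *static*
  clones inherit one fixed binary pattern per CpG and copy it onto reads
  with a small per-call error epsilon (cellular heterogeneity: low clone
  entropy, high pooled entropy);
* long reads spanning several CpG islands with a tunable read-level
  coordination strength rho: each read r draws a latent methylation
  propensity u_r ~ Beta(a, b) shared across its islands, and its calls in
  island c are Bernoulli(rho * u_r + (1 - rho) * v_rc) with v_rc an
  independent per-(read, island) Beta draw.  rho = 0 gives independent
  islands; rho = 1 gives fully coordinated molecules.

All outputs are deterministic functions of the configuration seed; each
generator stage uses its own named substream so stages can be re-run
independently without disturbing one another.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Feature, ReadProfile


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic methylome.

    Defaults describe a small genome with CpG-island architecture: a mean
    inter-CpG gap of 100 bp in the background, islands ten-fold denser,
    and read depths inside the 10-150x window the entropy analysis uses.
    """

    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int = 200_000

    # CpG spacing model
    mean_gap: int = 100
    cgi_density_multiplier: float = 10.0

    # feature layout
    n_cgis: int = 20
    cgi_length: int = 600

    # methylation regimes
    bimodal_low: float = 0.03
    bimodal_high: float = 0.85
    disordered_m: float = 0.5

    # clone model
    clone_model: str = "dynamic"  # "dynamic" | "static"
    n_clones: int = 8
    clone_coverage: int = 50
    clone_fourmers: int = 200
    static_error: float = 0.02  # per-call copy error epsilon of static clones

    # long-read model
    coordination: float = 0.0  # rho in [0, 1]
    beta_a: float = 2.0
    beta_b: float = 2.0
    n_blocks: int = 25
    cgis_per_block: int = 5
    cpgs_per_cgi: int = 20
    cgi_spacing: int = 2_000
    reads_per_block: int = 40

    # coverage and the nanopore-dialect likelihood model
    coverage: int = 50
    likelihood_low_fraction: float = 0.1

    # condition-pair (differential methylome) model
    hyper_epi_level: float = 0.05
    hyper_exe_level: float = 0.50
    neutral_level: float = 0.05
    excluded_epi_level: float = 0.25
    excluded_exe_level: float = 0.80
    condition_depth: int = 100
    condition_noise: bool = False

    def __post_init__(self) -> None:
        for name in (
            "bimodal_low", "bimodal_high", "disordered_m", "static_error",
            "coordination", "likelihood_low_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clone_model not in ("dynamic", "static"):
            raise ValueError(f"unknown clone model {self.clone_model!r}")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def rng(self, stage: str) -> np.random.Generator:
        """Named, seed-derived substream for one generator stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# genome / feature layout


def simulate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, np.ndarray], list[Feature]]:
    """CpG positions with geometric gaps, densified inside CGIs.

    CGIs are placed evenly along the chromosome; inter-CpG gaps are
    geometric with mean ``mean_gap`` outside islands and ``mean_gap /
    cgi_density_multiplier`` inside.  Returns per-chrom positions and the
    CGI features.
    """
    rng = config.rng("genome")
    spacing = config.chrom_length // (config.n_cgis + 1)
    cgis = []
    for i in range(config.n_cgis):
        start = spacing * (i + 1)
        end = min(start + config.cgi_length, config.chrom_length)
        cgis.append(Feature(f"cgi_{i:03d}", config.chrom, start, end, "cgi"))

    cgi_bounds = np.array([(c.start, c.end) for c in cgis])
    p_bg = min(1.0, 1.0 / config.mean_gap)
    p_cgi = min(1.0, config.cgi_density_multiplier / config.mean_gap)

    positions = []
    pos = int(rng.geometric(p_bg))
    while pos < config.chrom_length:
        positions.append(pos)
        in_cgi = bool(
            ((cgi_bounds[:, 0] <= pos) & (pos < cgi_bounds[:, 1])).any()
        ) if len(cgis) else False
        pos += int(rng.geometric(p_cgi if in_cgi else p_bg)) + 1
    return {config.chrom: np.array(positions, dtype=np.int64)}, cgis


# ---------------------------------------------------------------------------
# read-level regimes


def _iid_reads(
    chrom: str,
    positions: np.ndarray,
    m: float,
    n_reads: int,
    rng: np.random.Generator,
    prefix: str,
    start: int | None = None,
    end: int | None = None,
) -> list[ReadProfile]:
    positions = np.asarray(positions, dtype=np.int64)
    if start is None:
        start = int(positions[0])
    if end is None:
        end = int(positions[-1]) + 1
    states = rng.random((n_reads, positions.size)) < m
    return [
        ReadProfile(
            read_id=f"{prefix}_{i:05d}",
            chrom=chrom,
            start=start,
            end=end,
            positions=positions,
            states=states[i].astype(np.int8),
        )
        for i in range(n_reads)
    ]


def simulate_reads_disordered(
    config: SyntheticConfig,
    region: Feature | tuple[int, int] | None = None,
    positions: np.ndarray | None = None,
    m: float | None = None,
) -> list[ReadProfile]:
    """Disordered-regime reads: every call an independent Bernoulli(m) draw.

    Each of ``config.coverage`` reads spans the region and calls every CpG
    inside it.  Expected per-CpG rate is m; at m = 0.5 the 4-mer entropy
    approaches 1.
    """
    if positions is None:
        genome, _ = simulate_genome(config)
        positions = genome[config.chrom]
    positions = np.asarray(positions, dtype=np.int64)
    if region is not None:
        start, end = (region.start, region.end) if isinstance(region, Feature) else region
        positions = positions[(positions >= start) & (positions < end)]
    if positions.size == 0:
        return []
    if m is None:
        m = config.disordered_m
    return _iid_reads(
        config.chrom, positions, m, config.coverage,
        config.rng("disordered"), "rd",
    )


def simulate_reads_regime(
    config: SyntheticConfig, regime: str, **kwargs
) -> list[ReadProfile]:
    """Reads under a named regime: bimodal_low, bimodal_high or disordered."""
    levels = {
        "bimodal_low": config.bimodal_low,
        "bimodal_high": config.bimodal_high,
        "disordered": config.disordered_m,
    }
    if regime not in levels:
        raise ValueError(f"unknown regime {regime!r}")
    return simulate_reads_disordered(config, m=levels[regime], **kwargs)


# ---------------------------------------------------------------------------
# clones


def simulate_clones(
    config: SyntheticConfig,
) -> tuple[dict[str, list[ReadProfile]], pd.DataFrame]:
    """Per-clone reads under the dynamic or static inheritance model.

    The clone locus is a run of ``4 * clone_fourmers`` CpGs at 10 bp
    spacing; reads are emitted per disjoint 4-mer at exactly
    ``clone_coverage`` depth so the 4-mer universe is identical across
    clones.  Dynamic clones draw every call i.i.d. Bernoulli(m); static
    clones fix one inherited pattern per CpG (drawn once per clone with
    P(methylated) = m) and copy it onto each read with per-call error
    epsilon.  The truth table records the model and, for static clones,
    the inherited 4-mer patterns.
    """
    rng = config.rng("clones")
    n_cpgs = 4 * config.clone_fourmers
    positions = 1000 + 10 * np.arange(n_cpgs, dtype=np.int64)
    m = config.disordered_m
    eps = config.static_error

    reads_by_clone: dict[str, list[ReadProfile]] = {}
    truth_rows = []
    for ci in range(config.n_clones):
        clone = f"clone_{ci:02d}"
        if config.clone_model == "static":
            inherited = (rng.random(n_cpgs) < m).astype(np.int8)
        reads: list[ReadProfile] = []
        for j in range(config.clone_fourmers):
            sl = slice(4 * j, 4 * j + 4)
            pos = positions[sl]
            if config.clone_model == "dynamic":
                states = (rng.random((config.clone_coverage, 4)) < m).astype(np.int8)
            else:
                flips = rng.random((config.clone_coverage, 4)) < eps
                states = (inherited[sl][None, :] ^ flips).astype(np.int8)
            for r in range(config.clone_coverage):
                reads.append(
                    ReadProfile(
                        read_id=f"{clone}_fm{j:04d}_r{r:03d}",
                        chrom=config.chrom,
                        start=int(pos[0]),
                        end=int(pos[-1]) + 1,
                        positions=pos,
                        states=states[r],
                    )
                )
            truth_rows.append(
                {
                    "clone_id": clone,
                    "fourmer_index": j,
                    "model": config.clone_model,
                    "level": m,
                    "error": eps if config.clone_model == "static" else 0.0,
                    "inherited_pattern": (
                        "".join(map(str, inherited[sl].tolist()))
                        if config.clone_model == "static"
                        else ""
                    ),
                }
            )
        reads_by_clone[clone] = reads
    return reads_by_clone, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# long reads


def simulate_long_reads(
    config: SyntheticConfig,
) -> tuple[list[ReadProfile], list[Feature], pd.DataFrame]:
    """Long reads spanning blocks of CGIs with coordination strength rho.

    The genome is laid out as ``n_blocks`` independent blocks of
    ``cgis_per_block`` islands (``cpgs_per_cgi`` CpGs each, 10 bp spacing,
    islands ``cgi_spacing`` bp apart); every read spans its whole block.
    Returns the reads, the CGI features (island bounds snapped to their
    CpGs so a spanning read demonstrably contains the island), and a truth
    table flagging coordination per block.
    """
    rng = config.rng("longreads")
    rho = config.coordination
    reads: list[ReadProfile] = []
    cgis: list[Feature] = []
    truth_rows = []
    block_span = config.cgis_per_block * config.cgi_spacing + 10_000
    for b in range(config.n_blocks):
        origin = 10_000 + b * block_span
        block_pos = []
        block_cgis = []
        for k in range(config.cgis_per_block):
            start = origin + k * config.cgi_spacing
            pos = start + 10 * np.arange(config.cpgs_per_cgi, dtype=np.int64)
            block_pos.append(pos)
            cgi = Feature(
                f"blk{b:03d}_cgi{k}",
                config.chrom,
                int(pos[0]),
                int(pos[-1]) + 1,
                "cgi",
            )
            block_cgis.append(cgi)
            cgis.append(cgi)
        all_pos = np.concatenate(block_pos)
        read_start = int(all_pos[0]) - 100
        read_end = int(all_pos[-1]) + 100
        for r in range(config.reads_per_block):
            u = rng.beta(config.beta_a, config.beta_b)
            states = []
            for k in range(config.cgis_per_block):
                v = rng.beta(config.beta_a, config.beta_b)
                p = rho * u + (1.0 - rho) * v
                states.append(
                    (rng.random(config.cpgs_per_cgi) < p).astype(np.int8)
                )
            reads.append(
                ReadProfile(
                    read_id=f"blk{b:03d}_read{r:04d}",
                    chrom=config.chrom,
                    start=read_start,
                    end=read_end,
                    positions=all_pos,
                    states=np.concatenate(states),
                )
            )
        truth_rows.append(
            {
                "block": b,
                "cgi_ids": ",".join(c.id for c in block_cgis),
                "coordination": rho,
                "coordinated": rho > 0,
            }
        )
    return reads, cgis, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# condition pair (differential methylome)


def simulate_condition_pair(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two per-CpG rate tracks with planted differential CGIs.

    CGIs cycle through three planted classes: ``hyper`` (baseline low,
    gaining condition intermediate), ``neutral`` (low in both) and
    ``excluded`` (baseline already >= 0.2).  Background CpGs outside CGIs
    are highly methylated in both conditions, the somatic bimodal
    pattern.  With ``condition_noise`` unset, counts are the exact
    expectation (n_meth = round(level * depth)); otherwise n_meth is
    binomial at ``condition_depth``.  The truth table records the planted
    class and levels; only the ``hyper`` class is callable.
    """
    rng = config.rng("conditions")
    genome, cgis = simulate_genome(config)
    positions = genome[config.chrom]
    classes = ["hyper", "neutral", "excluded"]
    depth = config.condition_depth

    level_map = {
        "hyper": (config.hyper_epi_level, config.hyper_exe_level),
        "neutral": (config.neutral_level, config.neutral_level),
        "excluded": (config.excluded_epi_level, config.excluded_exe_level),
    }

    epi_level = np.full(positions.size, config.bimodal_high)
    exe_level = np.full(positions.size, config.bimodal_high)
    truth_rows = []
    for i, cgi in enumerate(cgis):
        cls = classes[i % len(classes)]
        epi_l, exe_l = level_map[cls]
        inside = (positions >= cgi.start) & (positions < cgi.end)
        epi_level[inside] = epi_l
        exe_level[inside] = exe_l
        truth_rows.append(
            {
                "cgi_id": cgi.id,
                "chrom": cgi.chrom,
                "start": cgi.start,
                "end": cgi.end,
                "planted_class": cls,
                "epi_level": epi_l,
                "exe_level": exe_l,
                "callable_hyper": cls == "hyper",
                "n_cpgs": int(inside.sum()),
            }
        )

    def track(levels: np.ndarray) -> pd.DataFrame:
        if config.condition_noise:
            n_meth = rng.binomial(depth, levels)
        else:
            n_meth = np.round(levels * depth).astype(np.int64)
        return pd.DataFrame(
            {
                "chrom": config.chrom,
                "pos": positions,
                "rate": n_meth / depth,
                "n_meth": n_meth,
                "n_total": depth,
            }
        )

    return track(epi_level), track(exe_level), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# nanopore-dialect likelihoods


def attach_likelihoods(
    reads: Sequence[ReadProfile], config: SyntheticConfig
):
    """Yield (read, likelihood array) pairs emulating caller confidences.

    A configurable fraction of calls falls below the 2.5 filter threshold
    (uniform on [0.5, 2.5)); the rest sit above it (2.5 + exponential).
    """
    rng = config.rng("likelihoods")
    thr = 2.5
    for read in reads:
        n = read.n_calls
        low = rng.random(n) < config.likelihood_low_fraction
        lik = np.where(
            low,
            rng.uniform(0.5, thr, size=n),
            thr + rng.exponential(3.0, size=n),
        )
        yield read, lik


def reads_to_call_rows(
    reads: Sequence[ReadProfile],
    likelihoods: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Flatten read profiles into the methylation-call TSV dialect."""
    rows = []
    for i, read in enumerate(reads):
        lik = likelihoods[i] if likelihoods is not None else None
        for j in range(read.n_calls):
            rows.append(
                (
                    read.read_id,
                    read.chrom,
                    int(read.positions[j]),
                    "+",
                    int(read.states[j]),
                    "." if lik is None else repr(float(lik[j])),
                )
            )
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos", "strand", "state", "likelihood"]
    )


def write_call_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
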