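"""End-to-end convenience workflows chaining simulation and analysis.

Thin orchestration over the library modules: each function generates a
synthetic dataset from a configuration, runs the corresponding analysis at
the package defaults, and returns the summary quantities of interest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clones import CloneSet, clone_bulk_contrast, insilico_bulk
from .concordance import cgi_pair_table
from .epiallele import enumerate_fourmers, epiallele_count_table
from .hypercgi import call_hyper_cgis, calls_to_frame
from .simulate import (
    SyntheticConfig,
    simulate_clones,
    simulate_condition_pair,
    simulate_genome,
    simulate_long_reads,
)


def run_clone_analysis(config: SyntheticConfig) -> dict:
    """Simulate clones, build the in-silico bulk, contrast the two.

    Returns the median per-clone 4-mer entropy, the median bulk entropy,
    and the full contrast table.  The 4-mer universe uses disjoint windows,
    matching the generator's read layout.
    """
    reads_by_clone, _ = simulate_clones(config)
    tables = {}
    for clone, reads in reads_by_clone.items():
        positions = np.unique(np.concatenate([r.positions for r in reads]))
        fourmers = enumerate_fourmers(
            {config.chrom: positions}, mode="disjoint")
        tables[clone] = epiallele_count_table(reads, fourmers)
    clone_set = CloneSet.from_tables(tables)
    bulk = insilico_bulk(clone_set, seed=config.seed)
    contrast = clone_bulk_contrast(clone_set, bulk)
    return {
        "median_clone_entropy": float(contrast["clone_entropy"].median()),
        "median_bulk_entropy": float(bulk["bulk_entropy"].median()),
        "contrast": contrast,
        "bulk": bulk,
    }


def run_concordance_analysis(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate long reads and compute the CGI-pair concordance table."""
    reads, cgis, _ = simulate_long_reads(config)
    return cgi_pair_table(reads, cgis, seed=config.seed)


def run_hypercgi_recovery(config: SyntheticConfig) -> dict:
    """Simulate a differential methylome and score recovery vs the truth.

    Precision and recall are computed for the ``hyper`` status against the
    planted callable set.
    """
    epi, exe, truth = simulate_condition_pair(config)
    _, cgis = simulate_genome(config)
    calls = calls_to_frame(call_hyper_cgis(cgis, epi, exe))
    merged = calls.merge(truth[["cgi_id", "callable_hyper"]], on="cgi_id")
    called = merged["status"] == "hyper"
    planted = merged["callable_hyper"]
    tp = int((called & planted).sum())
    precision = tp / int(called.sum()) if called.any() else float("nan")
    recall = tp / int(planted.sum()) if planted.any() else float("nan")
    return {"precision": precision, "recall": recall, "calls": merged}
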