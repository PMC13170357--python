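"""Standard evaluation scenarios: mapping fidelity and statistical
calibration of the fitness screen, computed end-to-end on synthetic data.

These are the package's own recovery benchmarks; tests and the
reproduction script both run them so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import fitness as fit
from . import mapping as mp
from . import synthetic as syn
from .counts import normalize_total


def mapping_fidelity(
    seed: int,
    n_insertions: int = 500,
    substitution_rate: float = 0.0,
    n_chromosomes: int = 7,
    genome_length: int = 1_000_000,
    reads_per_insertion: int = 10,
) -> dict:
    """Fraction of truth insertions recovered exactly (chromosome,
    position, strand) by the full junction-mapping pipeline.

    Insertions whose flank is truncated by a chromosome end are excluded
    from the denominator (the simulator flags them precisely so recovery
    can be scored on full-length evidence).
    """
    chrom_len = genome_length // n_chromosomes
    spec = syn.SyntheticGenomeSpec(
        n_chromosomes=n_chromosomes,
        chromosome_lengths=(chrom_len,) * n_chromosomes,
        n_genes=20 * n_chromosomes,
        gene_length_range=(1_000, 3_000),
        seed=seed,
    )
    genome = syn.simulate_genome(spec)
    truth = syn.simulate_insertions(genome, n_insertions, seed=seed + 1)
    params = syn.ReadSimulationParams(
        substitution_rate=substitution_rate,
        reads_per_insertion=reads_per_insertion,
        seed=seed + 2,
    )
    reads, _ = syn.simulate_tnseq_reads(truth, genome, params)
    pool, log = mp.map_tnseq(
        genome, syn.reads_as_tuples(reads), mp.MappingConfig(junction=params.junction_sequence)
    )

    L = params.flank_length
    full = truth.insertions[
        np.where(
            truth.insertions["strand"] == "+",
            truth.insertions["position"] + L - 1 <= chrom_len,
            truth.insertions["position"] - L >= 0,
        )
    ]
    singles = pool[pool["classification"] == "single"]
    merged = full.merge(singles, on="barcode", suffixes=("_true", "_obs"))
    exact = (
        (merged["chromosome_true"] == merged["chromosome_obs"])
        & (merged["position_true"] == merged["position_obs"])
        & (merged["strand_true"] == merged["strand_obs"])
    )
    return {
        "recovery_pct": 100.0 * float(exact.sum()) / len(full),
        "n": int(len(full)),
        "log": log,
    }


def _calibration_run(seed: int, n_planted: int, effect: float) -> dict:
    genome, truth = syn.calibration_scenario(
        seed=seed, n_planted=n_planted, effect=effect
    )
    table = syn.simulate_barseq_counts(
        truth, syn.CountSimulationParams(seed=seed + 3)
    )
    pool = syn.truth_pool_frame(truth)
    out = fit.fitness_pipeline(table, normalize_total(table), pool)
    res = out["results"]
    planted = set(truth.gene_effects)
    null = res[~res["gene_id"].isin(planted)]
    hit = res[res["gene_id"].isin(planted)]
    return {
        "null_hit_fraction": float(null["is_hit"].mean()) if len(null) else float("nan"),
        "planted_mean_log2fc": float(hit["mean_log2fc"].mean()) if len(hit) else float("nan"),
        "planted_hit_fraction": float(hit["is_hit"].mean()) if len(hit) else float("nan"),
        "genes_tested": int(len(res)),
    }


def fitness_calibration(
    seed: int, n_seeds: int = 20, n_planted: int = 10, effect: float = 2.0
) -> dict:
    """Averaged null false-call rate and planted-effect recovery over
    ``n_seeds`` independent simulated screens (200 genes x 5 barcodes x
    3 replicates per temperature, depth 10^6 per sample)."""
    null_fracs, means, recalls = [], [], []
    for i in range(n_seeds):
        run = _calibration_run(seed + 1000 * i, n_planted, effect)
        null_fracs.append(run["null_hit_fraction"])
        means.append(run["planted_mean_log2fc"])
        recalls.append(run["planted_hit_fraction"])
    return {
        "null_hit_pct": 100.0 * float(np.mean(null_fracs)),
        "planted_mean_log2fc": float(np.mean(means)),
        "planted_hit_recall_pct": 100.0 * float(np.mean(recalls)),
        "n_seeds": n_seeds,
    }
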