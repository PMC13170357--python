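"""BarSeq barcode extraction, counting, pool linkage and normalization.

Amplicon reads carry the random barcode between two constant priming
sites; the barcode is located by anchoring both flanks (each tolerating a
configurable number of mismatches, default 1). Counts are linked to
genomic insertion sites via the pool file and normalized by total-count
scaling to counts per million (CPM), which makes columns comparable
across sequencing depths while preserving within-sample proportions.
"""

from __future__ import annotations

import collections
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
import yaml

DEFAULT_NORM_TARGET = 1_000_000.0


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    temperature: float
    replicate: int
    batch: str = "batch1"


@dataclass
class BarcodeCountTable:
    """Barcode x sample matrix with sample metadata.

    ``counts`` is indexed by barcode with one column per sample_id;
    raw tables hold non-negative integers, normalized tables reals whose
    columns each sum to the common scaling target.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    normalized: bool = False
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        triples = [(s.temperature, s.replicate, s.batch) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(temperature, replicate, batch) triples must be unique")
        missing = [s.sample_id for s in self.samples if s.sample_id not in self.counts.columns]
        if missing:
            raise ValueError(f"samples missing from count matrix: {missing}")

    def sample_ids(self, temperature: float | None = None) -> list[str]:
        return [
            s.sample_id for s in self.samples
            if temperature is None or s.temperature == temperature
        ]


# ------------------------------------------------------------- extraction


def _first_match(read: str, pattern: str, max_mm: int, start: int = 0) -> int | None:
    for offset in range(start, len(read) - len(pattern) + 1):
        mm = 0
        for a, b in zip(read[offset : offset + len(pattern)], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return offset
    return None


def extract_barcode(
    read: str,
    left_flank: str,
    right_flank: str,
    barcode_length: int = 20,
    flank_mismatches: int = 1,
) -> str | None:
    """Extract the barcode bounded by the two constant priming sites.

    Scans for the first left-flank occurrence (within the mismatch
    tolerance) whose implied right flank is also consistent; returns the
    ``barcode_length``-nt window between them, or ``None`` when no such
    anchoring exists (including reads too short to hold the full layout).
    """
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    read = read.upper()
    left_flank, right_flank = left_flank.upper(), right_flank.upper()
    pos = 0
    while True:
        lo = _first_match(read, left_flank, flank_mismatches, start=pos)
        if lo is None:
            return None
        bc_start = lo + len(left_flank)
        bc_end = bc_start + barcode_length
        if bc_end + len(right_flank) <= len(read):
            mm = sum(
                a != b
                for a, b in zip(read[bc_end : bc_end + len(right_flank)], right_flank)
            )
            if mm <= flank_mismatches:
                return read[bc_start:bc_end]
        pos = lo + 1


# --------------------------------------------------------------- counting


def count_and_link(
    sample_barcodes: Mapping[str, Iterable[str]],
    pool: pd.DataFrame,
    samples: list[SampleMeta],
    rescue_hamming1: bool = False,
) -> BarcodeCountTable:
    """Count extracted barcodes per sample and link them to the pool.

    Observed barcodes are assigned to pool barcodes by exact match (with
    optional Hamming-1 rescue toward the pool, off by default since it can
    misassign between real neighbouring barcodes); barcodes absent from
    the pool are tallied as unassigned per sample. All pool barcodes
    appear as rows (zero-filled); the single-locus gene-level view is
    taken downstream.
    """
    pool_barcodes = list(pool["barcode"])
    pool_set = set(pool_barcodes)
    rescue_index: dict[str, str] = {}
    if rescue_hamming1:
        from .mapping import _hamming1_neighbors

        for bc in pool_barcodes:
            for nb in _hamming1_neighbors(bc):
                # ambiguous rescue targets are dropped
                rescue_index[nb] = "" if nb in rescue_index else bc

    data = {}
    unassigned: dict[str, int] = {}
    for meta in samples:
        counter: collections.Counter[str] = collections.Counter()
        miss = 0
        for bc in sample_barcodes.get(meta.sample_id, ()):
            if bc in pool_set:
                counter[bc] += 1
            elif rescue_hamming1 and rescue_index.get(bc):
                counter[rescue_index[bc]] += 1
            else:
                miss += 1
        data[meta.sample_id] = [counter.get(bc, 0) for bc in pool_barcodes]
        unassigned[meta.sample_id] = miss
    counts = pd.DataFrame(data, index=pd.Index(pool_barcodes, name="barcode"))
    return BarcodeCountTable(counts=counts, samples=list(samples), unassigned=unassigned)


# ----------------------------------------------------------- normalization


def normalize_total(
    table: BarcodeCountTable, target: float = DEFAULT_NORM_TARGET
) -> BarcodeCountTable:
    """Total-count scaling: each sample's column is scaled to sum to
    ``target`` (CPM for the default 10^6)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    norm = table.counts * (target / totals)
    return BarcodeCountTable(
        counts=norm, samples=list(table.samples), normalized=True,
        unassigned=dict(table.unassigned),
    )


# ------------------------------------------------------------- concordance


def replicate_concordance(table: BarcodeCountTable) -> pd.DataFrame:
    """Pairwise Pearson r and OLS R^2 between same-temperature replicates.

    Constant columns have undefined correlation and are reported as NaN
    rather than 0.
    """
    rows = []
    temps = sorted({s.temperature for s in table.samples})
    for temp in temps:
        ids = table.sample_ids(temp)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                x = table.counts[a].to_numpy(dtype=float)
                y = table.counts[b].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, r2 = np.nan, np.nan
                else:
                    r = scipy.stats.pearsonr(x, y).statistic
                    r2 = scipy.stats.linregress(x, y).rvalue ** 2
                rows.append(
                    {"temperature": temp, "sample_a": a, "sample_b": b,
                     "pearson_r": r, "r_squared": r2}
                )
    return pd.DataFrame(rows, columns=["temperature", "sample_a", "sample_b",
                                       "pearson_r", "r_squared"])


# --------------------------------------------------------------------- IO


def write_counts(table: BarcodeCountTable, path: str) -> None:
    table.counts.to_csv(path, sep="\t")


def read_counts(path: str, samples: list[SampleMeta], normalized: bool = False) -> BarcodeCountTable:
    counts = pd.read_csv(path, sep="\t", index_col="barcode")
    return BarcodeCountTable(counts=counts, samples=samples, normalized=normalized)


def read_sample_meta(path: str) -> list[SampleMeta]:
    """Sample metadata from TSV (sample_id, temperature, replicate, batch)
    or YAML (list of mappings with the same keys)."""
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
    else:
        entries = pd.read_csv(path, sep="\t").to_dict("records")
    return [
        SampleMeta(
            sample_id=str(e["sample_id"]),
            temperature=float(e["temperature"]),
            replicate=int(e["replicate"]),
            batch=str(e.get("batch", "batch1")),
        )
        for e in entries
    ]


def write_run_log(log: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
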