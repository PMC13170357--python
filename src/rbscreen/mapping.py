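"""TnSeq junction-read mapping: from raw junction reads plus a reference
genome to an annotated pool file.

Stages, in pipeline order:

1. junction detection in each read (Hamming scan, <= 2 mismatches);
2. barcode extraction (the barcode precedes the right-arm junction in the
   amplicon) and Hamming-1 barcode error collapsing;
3. local alignment of the genomic flank, uniqueness resolution (best hit
   must exceed the runner-up by >= 10 bitscore units);
4. near-position resolution (< 10 bp apart -> most abundantly supported
   locus wins) and insertion classification
   (single / multi-locus / concatameric / ambiguous);
5. gene assignment by interval intersection with the annotation, and
   50-kb insertion-density binning.

Only single-locus insertions supported by at least one uniquely mapped
read enter the pool file used for fitness analysis.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, GenomeAligner
from .genome import AnnotatedGenome

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_BIT_GAP = 10.0
DEFAULT_NEAR_BP = 10
DEFAULT_MIN_FLANK = 20
DEFAULT_BIN_SIZE = 50_000

POOL_COLUMNS = [
    "barcode", "chromosome", "position", "strand", "classification",
    "read_support", "gene_id", "multi_feature", "batch",
]


@dataclass(frozen=True)
class JunctionMatch:
    """Location of the T-DNA right-arm junction within one read."""

    read_id: str
    offset: int
    mismatches: int
    flank: str


@dataclass
class InsertionRecord:
    """One barcode's resolved insertion: a row of the pool file."""

    barcode: str
    classification: str
    read_support: int
    chromosome: str | None = None
    position: int | None = None
    strand: str | None = None
    gene_id: str = "intergenic"
    multi_feature: bool = False
    batch: str = ""

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")
        located = (
            self.chromosome is not None
            and self.position is not None
            and self.strand is not None
        )
        if (self.classification == "single") != located:
            raise ValueError(
                "single insertions must carry chromosome/position/strand; others must not"
            )


# --------------------------------------------------------------- junction


def find_junction(
    read: str,
    junction: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    read_id: str = "",
) -> JunctionMatch | None:
    """Locate the junction in a read by Hamming-distance window scan.

    Among windows within ``max_mismatches``, the one with the fewest
    mismatches wins; ties go to the lowest offset. Returns ``None`` when
    no window qualifies. The remainder of the read after the junction is
    the genomic flank.
    """
    if not read or not junction:
        raise ValueError("read and junction must be non-empty")
    if len(junction) > len(read):
        return None
    best_offset, best_mm = -1, max_mismatches + 1
    for offset in range(len(read) - len(junction) + 1):
        mm = 0
        for a, b in zip(read[offset : offset + len(junction)], junction):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_offset, best_mm = offset, mm
            if mm == 0:
                break
    if best_mm > max_mismatches:
        return None
    return JunctionMatch(
        read_id=read_id,
        offset=best_offset,
        mismatches=best_mm,
        flank=read[best_offset + len(junction) :],
    )


# ------------------------------------------------------- barcode collapse


def _hamming1_neighbors(barcode: str, alphabet: str = "ACGT") -> Iterable[str]:
    for i, orig in enumerate(barcode):
        for base in alphabet:
            if base != orig:
                yield barcode[:i] + base + barcode[i + 1 :]


def collapse_barcode_errors(barcode_reads: Mapping[str, int]) -> dict[str, int]:
    """Absorb single-base sequencing errors between barcodes.

    Every barcode at Hamming distance 1 from a strictly higher-count
    barcode is absorbed into it (counts summed); iterated to a fixed
    point. Among equally supported absorbers the lexicographically
    smaller barcode wins. Read counts are conserved.
    """
    counts = dict(barcode_reads)
    if not counts:
        return counts
    lengths = {len(b) for b in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths: {sorted(lengths)}")
    changed = True
    while changed:
        changed = False
        # smallest counts first so errors chain upward deterministically
        for bc in sorted(counts, key=lambda b: (counts[b], b)):
            if bc not in counts:
                continue
            absorbers = [
                nb for nb in _hamming1_neighbors(bc)
                if nb in counts and counts[nb] > counts[bc]
            ]
            if not absorbers:
                continue
            target = max(absorbers, key=lambda b: (counts[b], [-ord(c) for c in b]))
            counts[target] += counts.pop(bc)
            changed = True
    return counts


def collapse_mapping(barcode_reads: Mapping[str, int]) -> dict[str, str]:
    """Map each input barcode to its canonical (post-collapse) barcode."""
    counts = dict(barcode_reads)
    canon = {b: b for b in counts}
    collapsed = collapse_barcode_errors(counts)
    # replay absorption to recover the mapping: absorbed barcodes are the
    # ones missing from the collapsed dict; re-run the same deterministic
    # procedure tracking targets.
    counts = dict(barcode_reads)
    changed = True
    while changed:
        changed = False
        for bc in sorted(counts, key=lambda b: (counts[b], b)):
            if bc not in counts:
                continue
            absorbers = [
                nb for nb in _hamming1_neighbors(bc)
                if nb in counts and counts[nb] > counts[bc]
            ]
            if not absorbers:
                continue
            target = max(absorbers, key=lambda b: (counts[b], [-ord(c) for c in b]))
            counts[target] += counts.pop(bc)
            for orig, c in canon.items():
                if c == bc:
                    canon[orig] = target
            changed = True
    assert set(counts) == set(collapsed)
    return canon


# --------------------------------------------------- position resolution


def resolve_near_positions(
    positions: Mapping[int, int], near_bp: int = DEFAULT_NEAR_BP
) -> dict[int, int]:
    """Merge positions closer than ``near_bp`` into the most abundantly
    supported locus (ties: smaller coordinate); counts are summed.

    Operates within one (barcode, chromosome, strand) group.
    """
    remaining = dict(positions)
    resolved: dict[int, int] = {}
    while remaining:
        winner = max(remaining, key=lambda p: (remaining[p], -p))
        absorbed = [p for p in remaining if abs(p - winner) < near_bp]
        resolved[winner] = sum(remaining[p] for p in absorbed)
        for p in absorbed:
            del remaining[p]
    return resolved


def resolve_barcode_positions(
    barcode_positions: Mapping[str, Mapping[int, int]], near_bp: int = DEFAULT_NEAR_BP
) -> dict[str, tuple[int, int]]:
    """Per-barcode convenience wrapper: resolve each barcode's position
    list and return its best-supported locus."""
    out: dict[str, tuple[int, int]] = {}
    for bc, positions in barcode_positions.items():
        resolved = resolve_near_positions(positions, near_bp)
        best = max(resolved, key=lambda p: (resolved[p], -p))
        out[bc] = (best, resolved[best])
    return out


# --------------------------------------------------------------- uniqueness


def resolve_uniqueness(
    hits: Sequence[AlignmentHit], min_bit_gap: float = DEFAULT_MIN_BIT_GAP
) -> tuple[str, AlignmentHit | None]:
    """Classify a hit list as unique / multi-locus / unaligned.

    Unique iff there is exactly one hit, or the best bitscore exceeds the
    second best by at least ``min_bit_gap`` bits.
    """
    if not hits:
        return "unaligned", None
    ranked = sorted(hits, key=lambda h: -h.bitscore)
    if len(ranked) == 1 or ranked[0].bitscore - ranked[1].bitscore >= min_bit_gap:
        return "unique", ranked[0]
    return "multi-locus", None


# ------------------------------------------------------------- annotation


def annotate_insertions(
    records: list[InsertionRecord], genome: AnnotatedGenome
) -> list[InsertionRecord]:
    """Assign each single-locus insertion to the gene containing its
    position (1-based inclusive interval), or "intergenic"; positions in
    two or more overlapping features are flagged multi-feature and later
    excluded from gene-level fitness analysis."""
    for rec in records:
        if rec.classification != "single":
            continue
        genes = genome.genes_at(rec.chromosome, rec.position)
        if not genes:
            rec.gene_id, rec.multi_feature = "intergenic", False
        elif len(genes) == 1:
            rec.gene_id, rec.multi_feature = genes[0].gene_id, False
        else:
            rec.gene_id = ";".join(sorted(g.gene_id for g in genes))
            rec.multi_feature = True
    return records


# ----------------------------------------------------------------- density


def bin_density(
    records: Iterable[InsertionRecord],
    genome: AnnotatedGenome,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Insertion counts per ``bin_size`` window: bins [k*B+1, (k+1)*B]
    tile each chromosome; only single-locus insertions are counted."""
    counts: collections.Counter[tuple[str, int]] = collections.Counter()
    for rec in records:
        if rec.classification != "single":
            continue
        counts[(rec.chromosome, (rec.position - 1) // bin_size)] += 1
    rows = []
    for chrom, seq in genome.chromosomes.items():
        n_bins = (len(seq) + bin_size - 1) // bin_size
        for k in range(n_bins):
            rows.append(
                {
                    "chromosome": chrom,
                    "bin_start": k * bin_size + 1,
                    "bin_end": min((k + 1) * bin_size, len(seq)),
                    "insertion_count": counts.get((chrom, k), 0),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "bin_start", "bin_end", "insertion_count"])


# ---------------------------------------------------------------- pipeline


@dataclass
class MappingConfig:
    junction: str
    barcode_length: int = 20
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    min_flank: int = DEFAULT_MIN_FLANK
    min_identity: float = 95.0
    max_evalue: float = 0.1
    min_bit_gap: float = DEFAULT_MIN_BIT_GAP
    near_bp: int = DEFAULT_NEAR_BP
    tdna_sequence: str | None = None
    merge_shared_positions: bool = False


@dataclass
class _BarcodeEvidence:
    reads: int = 0
    insert_derived: int = 0
    multi: int = 0
    unaligned: int = 0
    loci: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)
    batches: set[str] = field(default_factory=set)


def classify_insertion(ev: _BarcodeEvidence, near_bp: int = DEFAULT_NEAR_BP) -> str:
    """Decide a barcode's classification from its aggregated read evidence.

    - concatameric: the flank evidence points at the T-DNA/vector itself
      (insert-derived reads outnumber uniquely genome-mapped reads);
    - ambiguous: uniquely mapped reads support conflicting loci (different
      chromosome/strand, or >= near_bp apart after resolution);
    - single: one resolved genomic locus with unique support;
    - multi-locus: every aligned read failed the uniqueness test.
    """
    unique_reads = sum(c for group in ev.loci.values() for c in group.values())
    if ev.insert_derived > unique_reads:
        return "concatameric"
    if ev.loci:
        resolved_groups = {
            key: resolve_near_positions(group, near_bp) for key, group in ev.loci.items()
        }
        n_loci = sum(len(g) for g in resolved_groups.values())
        if len(resolved_groups) > 1 or n_loci > 1:
            return "ambiguous"
        return "single"
    if ev.multi > 0:
        return "multi-locus"
    return "unaligned"


def map_tnseq(
    genome: AnnotatedGenome,
    reads: Iterable[tuple[str, str]] | Mapping[str, Iterable[tuple[str, str]]],
    config: MappingConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run the full junction-mapping pipeline.

    ``reads`` is an iterable of (read_id, sequence) for a single batch, or
    a mapping batch_name -> iterable for multiple batches; batches are
    concatenated before barcode collapsing (with per-batch provenance kept
    in the pool file), matching how independent transformation batches are
    combined into one pool.

    Returns (pool file DataFrame, run log dict).
    """
    if not isinstance(reads, Mapping):
        reads = {"batch1": reads}
    aligner = GenomeAligner(
        genome, min_identity=config.min_identity, max_evalue=config.max_evalue
    )
    tdna_aligner = None
    if config.tdna_sequence:
        tdna_aligner = GenomeAligner(
            AnnotatedGenome({"tdna": config.tdna_sequence.upper()}),
            min_identity=config.min_identity,
            max_evalue=config.max_evalue,
        )

    log = {
        "reads_total": 0,
        "no_junction": 0,
        "no_barcode": 0,
        "short_flank": 0,
        "unaligned_reads": 0,
    }
    # (barcode, batch) -> list of per-read outcomes
    read_outcomes: list[tuple[str, str, tuple]] = []
    barcode_read_counts: collections.Counter[str] = collections.Counter()

    for batch, batch_reads in reads.items():
        for read_id, seq in batch_reads:
            log["reads_total"] += 1
            jm = find_junction(seq.upper(), config.junction.upper(),
                               config.max_mismatches, read_id)
            if jm is None:
                log["no_junction"] += 1
                continue
            if jm.offset < config.barcode_length:
                log["no_barcode"] += 1
                continue
            barcode = seq[jm.offset - config.barcode_length : jm.offset].upper()
            if len(jm.flank) < config.min_flank:
                log["short_flank"] += 1
                continue
            hits = aligner.align(jm.flank)
            status, best = resolve_uniqueness(hits, config.min_bit_gap)
            insert_derived = False
            if tdna_aligner is not None:
                tdna_hits = tdna_aligner.align(jm.flank)
                best_genome = hits[0].bitscore if hits else float("-inf")
                if tdna_hits and tdna_hits[0].bitscore > best_genome:
                    insert_derived = True
            barcode_read_counts[barcode] += 1
            if insert_derived:
                outcome = ("insert",)
            elif status == "unique":
                # insertion position: first genomic base adjacent to the
                # right arm = the base the flank starts reading from
                pos = best.flank_origin()
                chrom_len = len(genome.chromosomes[best.chromosome])
                pos = min(max(pos, 1), chrom_len)
                outcome = ("unique", best.chromosome, best.strand, pos)
            elif status == "multi-locus":
                outcome = ("multi",)
            else:
                log["unaligned_reads"] += 1
                outcome = ("unaligned",)
            read_outcomes.append((barcode, batch, outcome))

    canon = collapse_mapping(barcode_read_counts)

    evidence: dict[str, _BarcodeEvidence] = collections.defaultdict(_BarcodeEvidence)
    for barcode, batch, outcome in read_outcomes:
        ev = evidence[canon[barcode]]
        ev.reads += 1
        ev.batches.add(batch)
        if outcome[0] == "insert":
            ev.insert_derived += 1
        elif outcome[0] == "unique":
            _, chrom, strand, pos = outcome
            group = ev.loci.setdefault((chrom, strand), {})
            group[pos] = group.get(pos, 0) + 1
        elif outcome[0] == "multi":
            ev.multi += 1
        else:
            ev.unaligned += 1

    records: list[InsertionRecord] = []
    for barcode in sorted(evidence):
        ev = evidence[barcode]
        cls = classify_insertion(ev, config.near_bp)
        batch_str = ",".join(sorted(ev.batches))
        if cls == "single":
            (chrom, strand), group = next(iter(ev.loci.items()))
            resolved = resolve_near_positions(group, config.near_bp)
            pos, support = next(iter(resolved.items()))
            records.append(
                InsertionRecord(
                    barcode=barcode, classification="single", read_support=support,
                    chromosome=chrom, position=pos, strand=strand, batch=batch_str,
                )
            )
        elif cls == "unaligned":
            continue  # no retained evidence for this barcode
        else:
            records.append(
                InsertionRecord(
                    barcode=barcode, classification=cls,
                    read_support=max(ev.reads, 1), batch=batch_str,
                )
            )

    annotate_insertions(records, genome)
    pool = records_to_frame(records)
    log["barcodes_collapsed"] = len(barcode_read_counts) - len(set(canon.values()))
    log["barcodes_total"] = len(set(canon.values()))
    for cls in ("single", "multi-locus", "concatameric", "ambiguous"):
        log[f"n_{cls.replace('-', '_')}"] = int((pool["classification"] == cls).sum())
    return pool, log


# -------------------------------------------------------------- pool file IO


def records_to_frame(records: Sequence[InsertionRecord]) -> pd.DataFrame:
    rows = [
        {
            "barcode": r.barcode,
            "chromosome": r.chromosome if r.chromosome is not None else "",
            "position": r.position,
            "strand": r.strand if r.strand is not None else "",
            "classification": r.classification,
            "read_support": r.read_support,
            "gene_id": r.gene_id,
            "multi_feature": r.multi_feature,
            "batch": r.batch,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=POOL_COLUMNS)
    df["position"] = df["position"].astype("Int64")
    return df


def write_pool(pool: pd.DataFrame, path: str) -> None:
    pool.to_csv(path, sep="\t", index=False)


def read_pool(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"barcode": str, "chromosome": str, "strand": str,
               "classification": str, "gene_id": str, "batch": str},
        keep_default_na=False,
    )
    df["position"] = pd.to_numeric(df["position"].replace("", np.nan)).astype("Int64")
    df["read_support"] = df["read_support"].astype(int)
    df["multi_feature"] = df["multi_feature"].astype(str).str.lower().isin(["true", "1"])
    return df[POOL_COLUMNS]
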