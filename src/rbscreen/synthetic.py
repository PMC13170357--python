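"""Synthetic genomes, insertion truth sets, junction reads and BarSeq
count tables with known statistical structure.

The generator emulates the data a randomly barcoded T-DNA mutagenesis
screen produces: a small multi-chromosome genome with non-overlapping
annotated genes; insertion sites drawn uniformly over the genome
(optionally with a transcriptional-hotspot window at elevated insertion
density); junction reads laid out as barcode + T-DNA right-arm junction +
genomic flank with i.i.d. substitution errors; and per-sample barcode
counts from lognormal mutant baseline abundances scaled by 2^(planted
gene effect) at the hot temperature, lognormal replicate noise, and
multinomial sequencing sampling at fixed depth. Every operation is a
pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import BarcodeCountTable, SampleMeta
from .genome import AnnotatedGenome, Gene, reverse_complement

BASES = np.array(list("ACGT"))
DEFAULT_BARCODE_LENGTH = 20
# arbitrary 30-nt right-arm junction used as the default cassette end
DEFAULT_JUNCTION = "CGTACGCTGCAGGTCGACGGATCCTCTAGA"


# ----------------------------------------------------------------- specs


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chromosome_lengths: tuple[int, ...] = (100_000, 100_000)
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (500, 2_000)
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must match n_chromosomes")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_genes < 0 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("bad gene parameters")


@dataclass(frozen=True)
class Hotspot:
    chromosome: str
    start: int
    end: int
    enrichment: float = 20.0


@dataclass
class SyntheticTruth:
    """Ground truth: insertion coordinates, planted gene effects and
    baseline mutant abundances."""

    insertions: pd.DataFrame  # barcode, chromosome, position, strand, gene_id
    gene_effects: dict[str, float]
    baseline_abundances: dict[str, float]
    hotspot: Hotspot | None = None

    def __post_init__(self) -> None:
        bcs = self.insertions["barcode"]
        if bcs.duplicated().any():
            raise ValueError("barcodes must be distinct")
        if len({len(b) for b in bcs}) > 1:
            raise ValueError("barcodes must have uniform length")


@dataclass(frozen=True)
class ReadSimulationParams:
    """Junction-read simulation.

    ``reads_per_insertion`` defaults to 10: junction libraries sequence
    each insertion many times over, and the barcode of a mutant is only
    identifiable when at least one of its reads carries the barcode
    without error, so single-digit coverage would misname a visible
    fraction of mutants at realistic error rates.
    """

    junction_sequence: str = DEFAULT_JUNCTION
    flank_length: int = 50
    substitution_rate: float = 0.0
    reads_per_insertion: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate < 0.25:
            raise ValueError("substitution_rate must lie in [0, 0.25)")
        if self.reads_per_insertion < 1 or self.flank_length < 1:
            raise ValueError("reads and flank length must be positive")


@dataclass(frozen=True)
class CountSimulationParams:
    """BarSeq sampling design.

    ``abundance_noise`` is the lognormal sigma of the per-(barcode,
    sample) replicate noise; the default 0.05 reproduces the replicate
    concordance observed in real pooled screens of this design (pairwise
    Pearson r above 0.99 between biological replicates). Counts are
    multinomial at fixed depth by default; ``negbin_dispersion`` switches
    to independent negative-binomial sampling per barcode (overdispersed,
    columns then only sum to depth in expectation).
    """

    temperatures: tuple[float, ...] = (37.0, 50.0)
    replicates_per_temperature: int = 3
    sequencing_depth: int = 1_000_000
    abundance_noise: float = 0.05
    hot_temperature: float = 50.0
    negbin_dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequencing_depth < 1 or self.replicates_per_temperature < 1:
            raise ValueError("depth and replicate counts must be positive")
        if self.abundance_noise < 0:
            raise ValueError("abundance_noise must be non-negative")
        if self.negbin_dispersion is not None and self.negbin_dispersion <= 0:
            raise ValueError("negbin_dispersion must be positive")


# ----------------------------------------------------------------- genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def simulate_genome(spec: SyntheticGenomeSpec) -> AnnotatedGenome:
    """Random genome with non-overlapping genes placed by distributing the
    inter-gene slack multinomially; deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chromosomes = {
        name: _random_sequence(rng, length, spec.gc_content)
        for name, length in zip(names, spec.chromosome_lengths)
    }
    # apportion genes to chromosomes proportionally to length
    lengths = np.array(spec.chromosome_lengths, dtype=float)
    ideal = spec.n_genes * lengths / lengths.sum()
    quota = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - quota))[: spec.n_genes - quota.sum()]:
        quota[i] += 1

    genes: list[Gene] = []
    gi = 0
    for name, length, n in zip(names, spec.chromosome_lengths, quota):
        if n == 0:
            continue
        glens = rng.integers(
            spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=n
        )
        slack = length - int(glens.sum())
        if slack < 0:
            raise ValueError(
                f"cannot pack {n} genes of total length {glens.sum()} into "
                f"{name} ({length} bp)"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 1
        for j in range(n):
            pos += int(gaps[j])
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"gene{gi:04d}", name, pos, pos + int(glens[j]) - 1, strand))
            pos += int(glens[j])
    return AnnotatedGenome(chromosomes=chromosomes, genes=genes)


# -------------------------------------------------------------- insertions


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(BASES[rng.integers(0, 4, size=length)])
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_insertions(
    genome: AnnotatedGenome,
    n: int,
    hotspot: Hotspot | None = None,
    seed: int = 0,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
    gene_sigma: float = 1.0,
    barcode_sigma: float = 0.25,
    gene_effects: Mapping[str, float] | None = None,
) -> SyntheticTruth:
    """Draw ``n`` insertion sites uniformly over the genome (each strand
    equally likely), optionally enriching a hotspot window by the given
    density multiplier.

    Baseline mutant abundances are hierarchical lognormals: a shared
    lognormal(0, ``gene_sigma``) factor per disrupted gene (mutants of
    the same gene have correlated pool representation, since disrupting
    the same gene perturbs growth similarly) times an independent
    lognormal(0, ``barcode_sigma``) factor per mutant (transformation
    and bottleneck variation); intergenic insertions each get their own
    gene-level factor. ``gene_effects`` plants per-gene log2 hot/cold
    effects recorded in the truth."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    weights = lengths.copy()
    if hotspot is not None:
        if hotspot.chromosome not in genome.chromosomes:
            raise ValueError(f"hotspot on unknown chromosome {hotspot.chromosome}")
        clen = len(genome.chromosomes[hotspot.chromosome])
        if not (1 <= hotspot.start <= hotspot.end <= clen):
            raise ValueError("hotspot interval outside chromosome bounds")
        extra = (hotspot.enrichment - 1.0) * (hotspot.end - hotspot.start + 1)
        weights[chroms.index(hotspot.chromosome)] += extra

    rows = []
    barcodes = _random_barcodes(rng, n, barcode_length)
    for i in range(n):
        ci = rng.choice(len(chroms), p=weights / weights.sum())
        chrom = chroms[ci]
        clen = int(lengths[ci])
        if hotspot is not None and chrom == hotspot.chromosome:
            span = hotspot.end - hotspot.start + 1
            p_hot = hotspot.enrichment * span / (clen - span + hotspot.enrichment * span)
            if rng.random() < p_hot:
                pos = int(rng.integers(hotspot.start, hotspot.end + 1))
            else:
                while True:
                    pos = int(rng.integers(1, clen + 1))
                    if not hotspot.start <= pos <= hotspot.end:
                        break
        else:
            pos = int(rng.integers(1, clen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        hit_genes = genome.genes_at(chrom, pos)
        gene_id = hit_genes[0].gene_id if len(hit_genes) == 1 else (
            ";".join(sorted(g.gene_id for g in hit_genes)) if hit_genes else "intergenic"
        )
        rows.append(
            {"barcode": barcodes[i], "chromosome": chrom, "position": pos,
             "strand": strand, "gene_id": gene_id}
        )
    insertions = pd.DataFrame(rows)
    group_keys = [
        row["gene_id"] if (row["gene_id"] != "intergenic" and ";" not in row["gene_id"])
        else f"__solo_{row['barcode']}"
        for row in rows
    ]
    group_factor: dict[str, float] = {}
    for key in group_keys:
        if key not in group_factor:
            group_factor[key] = float(np.exp(rng.normal(0.0, gene_sigma)))
    barcode_factors = np.exp(rng.normal(0.0, barcode_sigma, size=n))
    baselines = {
        bc: group_factor[key] * float(f)
        for bc, key, f in zip(barcodes, group_keys, barcode_factors)
    }
    return SyntheticTruth(
        insertions=insertions,
        gene_effects=dict(gene_effects or {}),
        baseline_abundances=baselines,
        hotspot=hotspot,
    )


def plant_effects(
    truth: SyntheticTruth,
    n_genes: int,
    effect: float,
    seed: int = 0,
    min_barcodes: int = 1,
) -> dict[str, float]:
    """Choose ``n_genes`` genic targets (with at least ``min_barcodes``
    insertions) and plant the given log2 effect on them; returns and
    records the effect map."""
    rng = np.random.default_rng(seed)
    counts = truth.insertions[
        (truth.insertions["gene_id"] != "intergenic")
        & (~truth.insertions["gene_id"].str.contains(";"))
    ]["gene_id"].value_counts()
    eligible = sorted(counts[counts >= min_barcodes].index)
    if len(eligible) < n_genes:
        raise ValueError(f"only {len(eligible)} eligible genes for {n_genes} effects")
    chosen = rng.choice(eligible, size=n_genes, replace=False)
    truth.gene_effects.update({g: float(effect) for g in chosen})
    return truth.gene_effects


# ------------------------------------------------------------ TnSeq reads


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(base_idx + shift) % 4]
    return "".join(arr)


def simulate_tnseq_reads(
    truth: SyntheticTruth,
    genome: AnnotatedGenome,
    params: ReadSimulationParams,
) -> tuple[list[SeqRecord], dict]:
    """Junction reads for every insertion: barcode + right-arm junction +
    genomic flank downstream of the insertion point on the recorded
    strand, with i.i.d. substitution errors over the whole read.

    The stored insertion position is the first genomic base adjacent to
    the right arm; on the minus strand the flank is the reverse
    complement of the reference interval ending at that position.
    Flanks truncated by a chromosome end are emitted but flagged in the
    returned log. Read names are opaque serial numbers (no truth leaks
    into the FASTQ).
    """
    shortest = min(len(s) for s in genome.chromosomes.values())
    if params.flank_length > shortest:
        raise ValueError("flank_length exceeds shortest chromosome")
    rng = np.random.default_rng(params.seed)
    records: list[SeqRecord] = []
    log = {"reads": 0, "truncated_reads": []}
    serial = 0
    for row in truth.insertions.itertuples(index=False):
        chrom_seq = genome.chromosomes[row.chromosome]
        pos, L = row.position, params.flank_length
        if row.strand == "+":
            flank = chrom_seq[pos - 1 : pos - 1 + L]
        else:
            flank = reverse_complement(chrom_seq[max(pos - L, 0) : pos])
        truncated = len(flank) < L
        for _ in range(params.reads_per_insertion):
            serial += 1
            read_id = f"read_{serial:07d}"
            seq = _apply_substitutions(
                rng, row.barcode + params.junction_sequence + flank,
                params.substitution_rate,
            )
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
            log["reads"] += 1
            if truncated:
                log["truncated_reads"].append(read_id)
    return records, log


def write_fastq(records: Sequence[SeqRecord], path: str) -> None:
    SeqIO.write(records, path, "fastq")


def reads_as_tuples(records: Sequence[SeqRecord]) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in records]


# ----------------------------------------------------------- BarSeq counts


def simulate_barseq_counts(
    truth: SyntheticTruth, params: CountSimulationParams
) -> BarcodeCountTable:
    """Per-sample barcode counts: multinomial sampling of ``depth`` reads
    over barcode proportions.

    At the hot temperature each barcode's lognormal baseline is scaled by
    2^(its gene's planted effect) (1 for genes without an effect); every
    (barcode, sample) additionally receives a lognormal noise multiplier
    of sigma ``abundance_noise`` before renormalization. Sample columns
    are named <temp>_<replicate>.
    """
    barcodes = list(truth.insertions["barcode"])
    missing = [b for b in barcodes if b not in truth.baseline_abundances]
    if missing:
        raise ValueError(f"{len(missing)} barcodes lack baseline abundances")
    baselines = np.array([truth.baseline_abundances[b] for b in barcodes])
    effects = np.array([
        truth.gene_effects.get(g, 0.0) for g in truth.insertions["gene_id"]
    ])
    rng = np.random.default_rng(params.seed)
    samples: list[SampleMeta] = []
    data: dict[str, np.ndarray] = {}
    for temp in params.temperatures:
        for rep in range(1, params.replicates_per_temperature + 1):
            sid = f"{temp:g}_{rep}"
            samples.append(SampleMeta(sample_id=sid, temperature=temp, replicate=rep))
            expected = baselines.copy()
            if temp == params.hot_temperature:
                expected = expected * np.exp2(effects)
            if params.abundance_noise > 0:
                expected = expected * np.exp(
                    rng.normal(0.0, params.abundance_noise, size=len(expected))
                )
            probs = expected / expected.sum()
            if params.negbin_dispersion is None:
                data[sid] = rng.multinomial(params.sequencing_depth, probs)
            else:
                mu = params.sequencing_depth * probs
                r = params.negbin_dispersion
                data[sid] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"))
    return BarcodeCountTable(counts=counts, samples=samples)


# ---------------------------------------------------------------- truth IO


def write_truth(truth: SyntheticTruth, insertions_path: str, effects_path: str) -> None:
    ins = truth.insertions.copy()
    ins["baseline_abundance"] = [
        truth.baseline_abundances[b] for b in ins["barcode"]
    ]
    ins.to_csv(insertions_path, sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "log2_effect": e} for g, e in sorted(truth.gene_effects.items())],
        columns=["gene_id", "log2_effect"],
    ).to_csv(effects_path, sep="\t", index=False)


def read_truth(insertions_path: str, effects_path: str | None = None) -> SyntheticTruth:
    ins = pd.read_csv(insertions_path, sep="\t")
    baselines = dict(zip(ins["barcode"], ins["baseline_abundance"]))
    effects: dict[str, float] = {}
    if effects_path is not None:
        eff = pd.read_csv(effects_path, sep="\t")
        if len(eff):
            effects = dict(zip(eff["gene_id"], eff["log2_effect"]))
    return SyntheticTruth(
        insertions=ins[["barcode", "chromosome", "position", "strand", "gene_id"]],
        gene_effects=effects,
        baseline_abundances=baselines,
    )


# ----------------------------------------------------- calibration design


def truth_pool_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Pool-file frame taken directly from the truth table (every barcode
    single-locus); used when count simulation is exercised without the
    read-mapping stage."""
    pool = truth.insertions.copy()
    pool["classification"] = "single"
    pool["read_support"] = 1
    pool["multi_feature"] = pool["gene_id"].str.contains(";")
    pool["batch"] = "batch1"
    return pool


def calibration_scenario(
    seed: int,
    n_genes: int = 200,
    barcodes_per_gene: int = 5,
    n_planted: int = 10,
    effect: float = 2.0,
    gene_sigma: float = 1.0,
    barcode_sigma: float = 0.25,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """The fitness-calibration design: ``n_genes`` genes each carrying
    ``barcodes_per_gene`` single-locus insertion mutants, with
    ``n_planted`` genes given a planted log2 hot/cold effect (0 planted
    genes = the null design). Baselines follow the hierarchical
    lognormal model of :func:`simulate_insertions`."""
    spec = SyntheticGenomeSpec(
        n_chromosomes=2,
        chromosome_lengths=(400_000, 400_000),
        n_genes=n_genes,
        gene_length_range=(1500, 3000),
        seed=seed,
    )
    genome = simulate_genome(spec)
    rng = np.random.default_rng(seed + 1)
    barcodes = _random_barcodes(rng, n_genes * barcodes_per_gene, barcode_length)
    rows = []
    i = 0
    for gene in genome.genes:
        for _ in range(barcodes_per_gene):
            rows.append(
                {
                    "barcode": barcodes[i],
                    "chromosome": gene.chromosome,
                    "position": int(rng.integers(gene.start, gene.end + 1)),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "gene_id": gene.gene_id,
                }
            )
            i += 1
    insertions = pd.DataFrame(rows)
    gene_factor = {
        g.gene_id: float(np.exp(rng.normal(0.0, gene_sigma))) for g in genome.genes
    }
    barcode_factor = np.exp(rng.normal(0.0, barcode_sigma, size=len(insertions)))
    baselines = {
        bc: gene_factor[gid] * float(f)
        for bc, gid, f in zip(insertions["barcode"], insertions["gene_id"], barcode_factor)
    }
    truth = SyntheticTruth(
        insertions=insertions, gene_effects={}, baseline_abundances=baselines
    )
    if n_planted:
        plant_effects(truth, n_planted, effect, seed=seed + 2,
                      min_barcodes=barcodes_per_gene)
    return genome, truth
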