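"""Reference genome container: chromosome sequences plus gene intervals.

All coordinates are 1-based inclusive (GFF3 convention) throughout the
package; a single convention avoids off-by-one drift between annotation
and insertion mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """One annotated gene interval, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Chromosome sequences and gene intervals; the coordinate frame for
    insertion mapping and gene assignment.
    """

    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene.chromosome not in self.chromosomes:
                raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chromosome}")
            if gene.end > len(self.chromosomes[gene.chromosome]):
                raise ValueError(
                    f"gene {gene.gene_id} extends past end of {gene.chromosome}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def genes_at(self, chromosome: str, position: int) -> list[Gene]:
        """All genes whose interval contains ``position`` (may be several
        when annotation features overlap)."""
        if chromosome not in self.chromosomes:
            raise ValueError(f"unknown chromosome {chromosome!r}")
        if not 1 <= position <= len(self.chromosomes[chromosome]):
            raise ValueError(f"position {position} outside {chromosome}")
        return [
            g for g in self.genes if g.chromosome == chromosome and g.contains(position)
        ]

    # ---------------------------------------------------------------- IO

    def write_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, path, "fasta")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                fh.write(
                    f"{g.chromosome}\trbscreen\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )

    @classmethod
    def from_files(cls, fasta_path: str, gff3_path: str | None = None) -> "AnnotatedGenome":
        chromosomes = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
        }
        genes: list[Gene] = []
        if gff3_path is not None:
            db = gffutils.create_db(
                gff3_path, dbfn=":memory:", force=True, keep_order=True,
                merge_strategy="create_unique",
            )
            for feat in db.features_of_type("gene"):
                gene_id = feat.attributes.get("ID", [feat.id])[0]
                genes.append(
                    Gene(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+")
                )
        return cls(chromosomes=chromosomes, genes=genes)

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        SeqIO.write(
            [SeqRecord(Seq(s), id=n, description="") for n, s in self.chromosomes.items()],
            buf,
            "fasta",
        )
        return buf.getvalue()
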