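"""Hermetic local aligner for short junction flanks.

Exact k-mer seeding plus ungapped extension, scored match +1 / mismatch -2,
with Karlin-Altschul bitscores and E-values:

    bits = (lambda * S - ln K) / ln 2
    E    = m * n * 2**(-bits)

where m is the query length and n the total genome length. Gapped
alignment is deliberately omitted: junction flanks are short and retained
hits must clear 95% identity anyway, so indel-tolerant alignment changes
nothing below the retention thresholds. An external aligner can be swapped
in as long as it honours the same hit contract (identity, E-value,
bitscore gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome import AnnotatedGenome, reverse_complement

# Karlin-Altschul parameters for the +1/-2 scoring scheme.
DEFAULT_LAMBDA = 1.28
DEFAULT_K = 0.46

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MAX_EVALUE = 0.1


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped local alignment of a query against the genome.

    ``start``/``end`` are 1-based inclusive genome coordinates with
    start <= end regardless of strand. ``query_start`` is the 0-based
    offset of the aligned region in the query (in query orientation).
    On the minus strand the query matches the reverse complement of
    [start, end].
    """

    chromosome: str
    start: int
    end: int
    strand: str
    score: int
    bitscore: float
    evalue: float
    identity: float
    query_start: int
    query_end: int

    def flank_origin(self) -> int:
        """Genome coordinate corresponding to query position 0.

        For a plus-strand hit the query reads left-to-right from here;
        for a minus-strand hit it reads right-to-left (the query is the
        reverse complement of the reference interval ending here).
        """
        if self.strand == "+":
            return self.start - self.query_start
        return self.end + self.query_start


class GenomeAligner:
    """k-mer indexed ungapped local aligner over an :class:`AnnotatedGenome`."""

    def __init__(
        self,
        genome: AnnotatedGenome,
        k: int = 12,
        match: int = 1,
        mismatch: int = -2,
        lambda_: float = DEFAULT_LAMBDA,
        karlin_k: float = DEFAULT_K,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        max_evalue: float = DEFAULT_MAX_EVALUE,
        xdrop: int = 10,
    ) -> None:
        self.genome = genome
        self.k = k
        self.match = match
        self.mismatch = mismatch
        self.lambda_ = lambda_
        self.karlin_k = karlin_k
        self.min_identity = min_identity
        self.max_evalue = max_evalue
        self.xdrop = xdrop
        self.db_length = genome.total_length
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    # ------------------------------------------------------------ scoring

    def bitscore(self, raw_score: int) -> float:
        return (self.lambda_ * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: int, query_length: int) -> float:
        return query_length * self.db_length * 2.0 ** (-self.bitscore(raw_score))

    # ---------------------------------------------------------- alignment

    def _extend(
        self, query: str, subject: str, qpos: int, spos: int
    ) -> tuple[int, int, int, int, int]:
        """Ungapped X-drop extension of an exact k-mer seed.

        Returns (q_lo, q_hi, s_lo, matches, score) with q_lo/q_hi the
        0-based half-open aligned query range.
        """
        # right extension from seed end
        score = self.k * self.match
        matches = self.k
        best = (score, qpos + self.k, matches)
        cur, cur_matches = score, matches
        qi, si = qpos + self.k, spos + self.k
        while qi < len(query) and si < len(subject):
            cur += self.match if query[qi] == subject[si] else self.mismatch
            cur_matches += query[qi] == subject[si]
            qi += 1
            si += 1
            if cur > best[0]:
                best = (cur, qi, cur_matches)
            elif best[0] - cur > self.xdrop:
                break
        score, q_hi, matches = best
        # left extension from seed start
        best_l = (score, qpos, matches)
        cur, cur_matches = score, matches
        qi, si = qpos - 1, spos - 1
        while qi >= 0 and si >= 0:
            cur += self.match if query[qi] == subject[si] else self.mismatch
            cur_matches += query[qi] == subject[si]
            if cur > best_l[0]:
                best_l = (cur, qi, cur_matches)
            elif best_l[0] - cur > self.xdrop:
                break
            qi -= 1
            si -= 1
        score, q_lo, matches = best_l
        s_lo = spos - (qpos - q_lo)
        return q_lo, q_hi, s_lo, matches, score

    def align(self, query: str) -> list[AlignmentHit]:
        """All hits passing the identity and E-value thresholds, sorted by
        bitscore descending (ties: chromosome, start, strand)."""
        query = query.upper()
        hits: dict[tuple[str, str, int, int], AlignmentHit] = {}
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            seen_diags: set[tuple[str, int]] = set()
            for qpos in range(len(q) - self.k + 1):
                kmer = q[qpos : qpos + self.k]
                for chrom, spos in self._index.get(kmer, ()):
                    diag = (chrom, spos - qpos)
                    if diag in seen_diags:
                        continue
                    seen_diags.add(diag)
                    subject = self.genome.chromosomes[chrom]
                    q_lo, q_hi, s_lo, matches, score = self._extend(q, subject, qpos, spos)
                    length = q_hi - q_lo
                    identity = 100.0 * matches / length
                    ev = self.evalue(score, len(query))
                    if identity < self.min_identity or ev > self.max_evalue:
                        continue
                    s_start, s_end = s_lo + 1, s_lo + length  # 1-based inclusive
                    if strand == "+":
                        qs, qe = q_lo, q_hi
                    else:  # report in original query orientation
                        qs, qe = len(query) - q_hi, len(query) - q_lo
                    key = (chrom, strand, s_start, s_end)
                    hit = AlignmentHit(
                        chromosome=chrom,
                        start=s_start,
                        end=s_end,
                        strand=strand,
                        score=score,
                        bitscore=self.bitscore(score),
                        evalue=ev,
                        identity=identity,
                        query_start=qs,
                        query_end=qe,
                    )
                    prev = hits.get(key)
                    if prev is None or hit.score > prev.score:
                        hits[key] = hit
        return sorted(
            hits.values(),
            key=lambda h: (-h.bitscore, h.chromosome, h.start, h.strand),
        )


def filter_hits(
    hits: list[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[AlignmentHit]:
    """Re-apply retention thresholds; tightening them never grows the set."""
    return [h for h in hits if h.identity >= min_identity and h.evalue <= max_evalue]
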