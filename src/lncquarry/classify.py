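"""Compare assembled transcripts against a reference annotation.

Implements a reduced, gffcompare-style class-code vocabulary:

* ``=``  full intron-chain match to a reference transcript (mono-exon
  transcripts: same-strand exon overlap >= 80% reciprocal),
* ``i``  every exon strictly inside introns of one reference transcript,
* ``u``  intergenic: no base overlaps any reference gene body,
* ``o``  any other overlap.

Also provides spliced-sequence extraction and the nearest
protein-coding-neighbour search used by the distance filter and cis-target
assignment.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import (
    BIOTYPE_PROTEIN_CODING,
    GenomicInterval,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

CODE_MATCH = "="
CODE_INTERGENIC = "u"
CODE_INTRONIC = "i"
CODE_OTHER = "o"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClassCode:
    code: str
    matched_reference_id: str | None = None


@dataclass(frozen=True)
class NeighborReport:
    """Nearest protein-coding gene on each side of a query transcript.

    Distances count the bases strictly between the closest boundaries
    (0 when touching or overlapping); a side with no gene inside the
    search window is reported as ``None``.
    """

    transcript_id: str
    left_gene: str | None
    left_distance: int | None
    right_gene: str | None
    right_distance: int | None
    window: int


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    biotype: str


class ReferenceIndex:
    """Interval indexes over a reference annotation.

    Gene bodies are the per-gene span over all transcripts; a gene is
    protein-coding if any of its transcripts is.
    """

    def __init__(self, reference: list[TranscriptModel]):
        self.transcripts = list(reference)
        self._tx_trees: dict[str, IntervalTree] = {}
        for tx in reference:
            iv = tx.interval
            self._tx_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, tx)
        genes: dict[str, list[TranscriptModel]] = {}
        for tx in reference:
            genes.setdefault(tx.gene_id, []).append(tx)
        self.genes: dict[str, GeneRecord] = {}
        for gid, txs in genes.items():
            chroms = {t.chrom for t in txs}
            if len(chroms) > 1:
                raise ValueError(f"gene {gid} spans multiple chromosomes")
            start = min(t.interval.start for t in txs)
            end = max(t.interval.end for t in txs)
            biotype = txs[0].biotype
            for t in txs:
                if t.biotype == BIOTYPE_PROTEIN_CODING:
                    biotype = BIOTYPE_PROTEIN_CODING
            self.genes[gid] = GeneRecord(
                gid, GenomicInterval(txs[0].chrom, start, end, txs[0].strand),
                biotype)
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            self._gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end + 1, g)
        # per-chromosome sorted views of protein-coding genes for the
        # nearest-neighbour search
        self._pc_by_end: dict[str, list[tuple[int, str, GeneRecord]]] = {}
        self._pc_by_start: dict[str, list[tuple[int, str, GeneRecord]]] = {}
        for g in self.genes.values():
            if g.biotype != BIOTYPE_PROTEIN_CODING:
                continue
            self._pc_by_end.setdefault(g.interval.chrom, []).append(
                (g.interval.end, g.gene_id, g))
            self._pc_by_start.setdefault(g.interval.chrom, []).append(
                (g.interval.start, g.gene_id, g))
        for lst in self._pc_by_end.values():
            lst.sort()
        for lst in self._pc_by_start.values():
            lst.sort()

    def overlapping_transcripts(self, iv: GenomicInterval) -> list[TranscriptModel]:
        tree = self._tx_trees.get(iv.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(iv.start, iv.end + 1)]

    def overlapping_genes(self, iv: GenomicInterval) -> list[GeneRecord]:
        tree = self._gene_trees.get(iv.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(iv.start, iv.end + 1)]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._gene_trees


def extract_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Concatenate exon subsequences 5'->3'; minus-strand transcripts are
    reverse-complemented.  Unstranded transcripts are returned in plus
    orientation."""
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} absent from genome")
    chrom_seq = genome[model.chrom]
    parts = []
    for e in model.exons:
        if e.end > len(chrom_seq):
            raise ValueError(
                f"{model.transcript_id}: exon {e.start}-{e.end} beyond "
                f"{model.chrom} end ({len(chrom_seq)})")
        parts.append(chrom_seq[e.start - 1:e.end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _strand_compatible(a: str, b: str) -> bool:
    # unstranded queries fall back to matching either strand
    return a == b or a == "." or b == "."


def _is_full_match(query: TranscriptModel, ref: TranscriptModel) -> bool:
    if not _strand_compatible(query.strand, ref.strand):
        return False
    if query.exon_count > 1 or ref.exon_count > 1:
        if query.exon_count != ref.exon_count:
            return False
        return query.intron_chain() == ref.intron_chain()
    # mono-exon both: >= 80% reciprocal overlap
    q, r = query.interval, ref.interval
    ov = q.overlap_length(r)
    return ov >= 0.8 * q.length and ov >= 0.8 * r.length


def _is_intronic(query: TranscriptModel, ref: TranscriptModel) -> bool:
    introns = ref.introns
    if not introns:
        return False
    for exon in query.exons:
        if not any(i.start <= exon.start and exon.end <= i.end
                   for i in introns):
            return False
    return True


def assign_class_code(model: TranscriptModel,
                      reference: ReferenceIndex) -> ClassCode:
    """Assign the reduced class code for one assembled transcript.

    A query on a chromosome absent from the reference is classified ``u``
    with a warning.  Intron containment ignores the reference strand (the
    host relation is positional); the ``=`` match requires strand
    compatibility.
    """
    iv = model.interval
    if not reference.has_chrom(iv.chrom):
        logger.warning("query %s on chromosome %s absent from reference; "
                       "classified 'u'", model.transcript_id, iv.chrom)
        return ClassCode(CODE_INTERGENIC)
    candidates = sorted(reference.overlapping_transcripts(iv),
                        key=lambda t: t.transcript_id)
    for ref in candidates:
        if _is_full_match(model, ref):
            return ClassCode(CODE_MATCH, ref.transcript_id)
    genes = reference.overlapping_genes(iv)
    if not genes:
        return ClassCode(CODE_INTERGENIC)
    for ref in candidates:
        if _is_intronic(model, ref):
            return ClassCode(CODE_INTRONIC, ref.transcript_id)
    return ClassCode(CODE_OTHER, min(g.gene_id for g in genes))


def nearest_protein_coding(model: TranscriptModel,
                           reference: ReferenceIndex,
                           window: int) -> NeighborReport:
    """Nearest protein-coding gene body on each side, within ``window`` nt.

    A gene overlapping the query counts on both sides with distance 0.
    Equidistant candidates break ties by lexicographically smaller
    gene_id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    iv = model.interval
    best_left: tuple[int, str] | None = None
    best_right: tuple[int, str] | None = None

    for g in reference.overlapping_genes(iv):
        if g.biotype != BIOTYPE_PROTEIN_CODING:
            continue
        cand = (0, g.gene_id)
        if best_left is None or cand < best_left:
            best_left = cand
        if best_right is None or cand < best_right:
            best_right = cand

    by_end = reference._pc_by_end.get(iv.chrom, [])
    idx = bisect.bisect_left(by_end, (iv.start, "", None)) - 1
    if idx >= 0:
        far_end = by_end[idx][0]
        dist = iv.start - far_end - 1
        if dist <= window:
            j = idx
            while j >= 0 and by_end[j][0] == far_end:
                cand = (dist, by_end[j][1])
                if best_left is None or cand < best_left:
                    best_left = cand
                j -= 1

    by_start = reference._pc_by_start.get(iv.chrom, [])
    idx = bisect.bisect_right(by_start, (iv.end + 1, "", None))
    # skip genes starting inside the query (they overlap and were handled)
    while idx < len(by_start) and by_start[idx][0] <= iv.end:
        idx += 1
    if idx < len(by_start):
        near_start = by_start[idx][0]
        dist = near_start - iv.end - 1
        if dist <= window:
            j = idx
            while j < len(by_start) and by_start[j][0] == near_start:
                cand = (dist, by_start[j][1])
                if best_right is None or cand < best_right:
                    best_right = cand
                j += 1

    return NeighborReport(
        model.transcript_id,
        best_left[1] if best_left else None,
        best_left[0] if best_left else None,
        best_right[1] if best_right else None,
        best_right[0] if best_right else None,
        window)


SUBTYPE_LINCRNA = "lincRNA"
SUBTYPE_ILNCRNA = "ilncRNA"


def subtype_lncrna(class_code: ClassCode | str) -> str:
    """Map class code to lncRNA subtype: 'u' -> lincRNA, 'i' -> ilncRNA."""
    code = class_code.code if isinstance(class_code, ClassCode) else class_code
    if code == CODE_INTERGENIC:
        return SUBTYPE_LINCRNA
    if code == CODE_INTRONIC:
        return SUBTYPE_ILNCRNA
    raise ValueError(
        f"class code {code!r} is not a lncRNA candidate (expected 'u' or 'i')")
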