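"""Readers and writers for the external formats the pipeline touches.

One coordinate convention everywhere: internal intervals are 1-based
inclusive.  BED input (0-based half-open) is converted here, at the
boundary, and nowhere else.  Chromosome names are taken verbatim; an
optional synonym map can be applied on read.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    BIOTYPE_ANNOTATED_LNCRNA,
    BIOTYPE_PROTEIN_CODING,
    BIOTYPE_UNKNOWN,
    GeneSet,
    GenomicInterval,
    HitRecord,
    IntegrityError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_NUCLEOTIDES = set("ACGTN")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# biotype attribute values mapped onto the internal three-way scheme
_BIOTYPE_MAP = {
    "protein_coding": BIOTYPE_PROTEIN_CODING,
    "lncRNA": BIOTYPE_ANNOTATED_LNCRNA,
    "lincRNA": BIOTYPE_ANNOTATED_LNCRNA,
    "antisense": BIOTYPE_ANNOTATED_LNCRNA,
    "annotated_lncRNA": BIOTYPE_ANNOTATED_LNCRNA,
}


class GtfParseError(ValueError):
    """A malformed GTF line; the message names the offending line number."""


def parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path,
             feature_filter: tuple[str, ...] = ("exon",),
             chrom_synonyms: dict[str, str] | None = None,
             ) -> list[TranscriptModel]:
    """Group GTF exon rows into :class:`TranscriptModel` objects.

    Biotype is read from ``gene_biotype``/``transcript_biotype`` when
    present, else ``unknown``.  Transcripts are returned in order of first
    appearance.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = cols
            if feature not in feature_filter:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            att = parse_gtf_attributes(attrs)
            tid = att.get("transcript_id")
            gid = att.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path}:{lineno}: missing transcript_id/gene_id attribute")
            if chrom_synonyms:
                chrom = chrom_synonyms.get(chrom, chrom)
            try:
                exon = GenomicInterval(chrom, start_i, end_i, strand)
            except IntegrityError as exc:
                raise IntegrityError(f"{path}:{lineno}: {exc}") from exc
            biotype = _BIOTYPE_MAP.get(
                att.get("gene_biotype", att.get("transcript_biotype", "")),
                BIOTYPE_UNKNOWN)
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = {"gene_id": gid, "exons": [exon],
                               "biotype": biotype}
                order.append(tid)
            else:
                if exon.strand != rec["exons"][0].strand:
                    raise IntegrityError(
                        f"{path}:{lineno}: transcript {tid} has exons on "
                        f"conflicting strands")
                rec["exons"].append(exon)
                if biotype != BIOTYPE_UNKNOWN:
                    rec["biotype"] = biotype
    return [TranscriptModel(tid, per_tx[tid]["gene_id"], per_tx[tid]["exons"],
                            per_tx[tid]["biotype"])
            for tid in order]


_BIOTYPE_OUT = {
    BIOTYPE_PROTEIN_CODING: "protein_coding",
    BIOTYPE_ANNOTATED_LNCRNA: "lncRNA",
    BIOTYPE_UNKNOWN: "unknown",
}


def write_gtf(models: list[TranscriptModel], path: str | Path,
              source: str = "lncquarry") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                     f'gene_biotype "{_BIOTYPE_OUT[m.biotype]}";')
            iv = m.interval
            fh.write("\t".join([iv.chrom, source, "transcript", str(iv.start),
                                str(iv.end), ".", iv.strand, ".", attrs]) + "\n")
            for e in m.exons:
                fh.write("\t".join([e.chrom, source, "exon", str(e.start),
                                    str(e.end), ".", e.strand, ".", attrs]) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: upper-cased sequence}; rejects duplicate headers and
    characters outside A/C/G/T/N."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise IntegrityError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise IntegrityError(
                f"{path}: sequence {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_interval_table(path: str | Path, schema: str,
                        ) -> list[tuple[GenomicInterval, list[str]]]:
    """Read a BED3+ (``schema="bed"``) or 1-based TSV (``schema="one_based"``)
    interval file; extra columns are returned verbatim as attributes."""
    if schema not in ("bed", "one_based"):
        raise ValueError(f"unknown interval schema {schema!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GtfParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start < 0 or end < 0:
                raise IntegrityError(f"{path}:{lineno}: negative coordinates")
            if schema == "bed":
                if end <= start:
                    raise IntegrityError(
                        f"{path}:{lineno}: zero/negative-length BED interval")
                iv = GenomicInterval(chrom, start + 1, end)
            else:
                iv = GenomicInterval(chrom, start, end)
            out.append((iv, cols[3:]))
    return out


def interval_to_bed(iv: GenomicInterval) -> tuple[str, int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return iv.chrom, iv.start - 1, iv.end


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, s, e = interval_to_bed(iv)
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """One gene set per line: id, description, >= 1 member; duplicate
    members on a line are deduplicated with a warning."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GtfParseError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f">= 1 member")
            members = [c for c in cols[2:] if c]
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members in set %s "
                               "deduplicated", path, lineno, cols[0])
            sets.append(GeneSet(cols[0], cols[1], frozenset(members)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)])
                     + "\n")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """12-column blast-tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 12 blast-tabular columns")
            hits.append(HitRecord(cols[0], cols[1], float(cols[2]),
                                  int(cols[3]), float(cols[11]),
                                  float(cols[10])))
    return hits


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                str(h.alignment_length), "0", "0", "0", "0", "0", "0",
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}"]) + "\n")


def read_position_table(path: str | Path) -> dict[str, GenomicInterval]:
    """TSV of (id, chrom, start, end[, strand]) with 1-based coordinates."""
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise GtfParseError(f"{path}:{lineno}: need id, chrom, "
                                    f"start, end")
            strand = cols[4] if len(cols) > 4 else "."
            if cols[0] in out:
                raise IntegrityError(f"{path}:{lineno}: duplicate id {cols[0]!r}")
            out[cols[0]] = GenomicInterval(cols[1], int(cols[2]), int(cols[3]),
                                           strand)
    return out


def write_position_table(positions: dict[str, GenomicInterval],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in positions.items():
            fh.write(f"{name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
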