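"""Co-localization of lncRNA loci with quantitative-trait-locus intervals.

QTL input is a flat TSV (qtl_id, trait, chrom, start, end; 1-based
inclusive).  The lncRNA locus used for overlap is the transcript interval
(QTL intervals are coarse), and overlap means >= 1 shared base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .models import GenomicInterval, IntegrityError


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    trait: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.trait:
            raise IntegrityError(f"QTL {self.qtl_id}: empty trait name")


@dataclass(frozen=True)
class QtlAssignment:
    lnc_id: str
    qtl_id: str
    trait: str
    overlap_length: int


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: need qtl_id, trait, "
                                 f"chrom, start, end")
            out.append(QTLRecord(cols[0], cols[1],
                                 GenomicInterval(cols[2], int(cols[3]),
                                                 int(cols[4]))))
    return out


def write_qtl_table(records: list[QTLRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.qtl_id}\t{r.trait}\t{r.interval.chrom}\t"
                     f"{r.interval.start}\t{r.interval.end}\n")


def overlap_qtls(lnc_entries: list[tuple[str, GenomicInterval]],
                 qtl_records: list[QTLRecord]) -> list[QtlAssignment]:
    """All lncRNA x QTL pairs sharing >= 1 base (1-based inclusive
    arithmetic); a lncRNA may match many QTLs and vice versa."""
    trees: dict[str, IntervalTree] = {}
    for q in qtl_records:
        trees.setdefault(q.interval.chrom, IntervalTree()).addi(
            q.interval.start, q.interval.end + 1, q)
    out = []
    for lnc_id, iv in lnc_entries:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end + 1),
                          key=lambda h: h.data.qtl_id):
            q: QTLRecord = hit.data
            out.append(QtlAssignment(lnc_id, q.qtl_id, q.trait,
                                     iv.overlap_length(q.interval)))
    out.sort(key=lambda a: (a.lnc_id, a.qtl_id))
    return out


def multi_qtl_report(assignments: list[QtlAssignment], min_qtls: int = 2,
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """lncRNAs overlapping >= ``min_qtls`` QTLs, sorted by QTL count
    descending then id, plus a per-trait assignment count summary."""
    per_lnc: dict[str, list[str]] = {}
    for a in assignments:
        per_lnc.setdefault(a.lnc_id, []).append(a.qtl_id)
    rows = [{"lnc_id": lnc, "n_qtls": len(set(qtls)),
             "qtl_ids": ",".join(sorted(set(qtls)))}
            for lnc, qtls in per_lnc.items() if len(set(qtls)) >= min_qtls]
    report = pd.DataFrame(rows, columns=["lnc_id", "n_qtls", "qtl_ids"])
    if not report.empty:
        report = report.sort_values(["n_qtls", "lnc_id"],
                                    ascending=[False, True],
                                    ignore_index=True)
    trait_counts = pd.Series(
        [a.trait for a in assignments], dtype=object
    ).value_counts().sort_index()
    return report, trait_counts
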