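"""The lncRNA discovery cascade with per-transcript provenance.

Canonical stage order (first failure is terminal):

1.  ``class_code``      — compare to the reference: '=' transcripts leave
    as annotated mRNA/lncRNA (by reference biotype), 'o' as other
    overlap; only 'u'/'i' continue.
2.  ``known_lnc``       — homology against the known-lncRNA catalogue at
    E < 1e-5 assigns provenance "known" (not a removal).
3.  ``min_length``      — keep only transcripts > 200 nt.
4.  ``monoexon_length`` — drop mono-exon transcripts > 10,000 nt.
5.  ``repeat_overlap``  — drop transcripts with exonic overlap of a
    repeat interval (>= 1 base by default).
6.  ``expression``      — keep FPKM >= 1 in >= 2 samples.
7.  ``exclusion_db``    — drop transcripts hitting any exclusion
    database (protein/miRNA/structural RNA/domain tables) at E < 1e-5.
8.  ``coding_vote``     — drop transcripts called coding by >= 3 scorers.
9.  ``orf_length``      — drop transcripts with a complete ORF > 300 aa.
10. ``gene_distance``   — intergenic ('u') only: drop transcripts
    < 1 kb from a protein-coding gene.

Survivors are novel lncRNAs, subtyped lincRNA ('u') / ilncRNA ('i').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    CODE_INTERGENIC,
    CODE_INTRONIC,
    CODE_MATCH,
    CODE_OTHER,
    ReferenceIndex,
    SUBTYPE_ILNCRNA,
    SUBTYPE_LINCRNA,
    assign_class_code,
    extract_sequence,
    nearest_protein_coding,
    subtype_lncrna,
)
from .coding import (
    SearchParams,
    FICKETT_NONCODING_BOUND,
    best_hits,
    fickett_score,
    find_longest_orf,
    hexamer_score,
    homology_search,
    orf_fraction,
    train_hexamer_model,
    vote_coding,
)
from .expression import ExpressionMatrix
from .models import (
    BIOTYPE_ANNOTATED_LNCRNA,
    BIOTYPE_PROTEIN_CODING,
    GenomicInterval,
    HitRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

STAGE_CLASS_CODE = "class_code"
STAGE_KNOWN = "known_lnc"
STAGE_MIN_LENGTH = "min_length"
STAGE_MONOEXON = "monoexon_length"
STAGE_REPEAT = "repeat_overlap"
STAGE_EXPRESSION = "expression"
STAGE_EXCLUSION = "exclusion_db"
STAGE_CODING_VOTE = "coding_vote"
STAGE_ORF = "orf_length"
STAGE_DISTANCE = "gene_distance"

STAGE_ORDER = (STAGE_CLASS_CODE, STAGE_KNOWN, STAGE_MIN_LENGTH,
               STAGE_MONOEXON, STAGE_REPEAT, STAGE_EXPRESSION,
               STAGE_EXCLUSION, STAGE_CODING_VOTE, STAGE_ORF,
               STAGE_DISTANCE)

# terminal categories
TERM_ANNOTATED_MRNA = "annotated_mRNA"
TERM_ANNOTATED_LNC = "annotated_lncRNA"
TERM_OTHER_OVERLAP = "other_overlap"
TERM_KNOWN_LINC = "known_lincRNA"
TERM_KNOWN_ILNC = "known_ilncRNA"
TERM_NOVEL_LINC = "novel_lincRNA"
TERM_NOVEL_ILNC = "novel_ilncRNA"

PROV_ANNOTATED = "annotated"
PROV_KNOWN = "known"
PROV_NOVEL = "novel"


@dataclass
class StageRecord:
    stage: str
    metric: str
    decision: str          # "pass" | "fail"


@dataclass
class FilterTrace:
    """Ordered audit trail of one transcript through the cascade."""

    transcript_id: str
    records: list[StageRecord] = field(default_factory=list)
    terminal_category: str | None = None

    def add(self, stage: str, metric, passed: bool) -> None:
        if self.records and self.records[-1].decision == "fail":
            raise RuntimeError(
                f"{self.transcript_id}: stage {stage} evaluated after a "
                f"terminal failure")
        self.records.append(StageRecord(stage, str(metric),
                                        "pass" if passed else "fail"))
        if not passed and self.terminal_category is None:
            # callers overwrite for the annotated/known branchings
            self.terminal_category = f"removed_{stage}"

    @property
    def failed_stage(self) -> str | None:
        for rec in self.records:
            if rec.decision == "fail":
                return rec.stage
        return None


@dataclass(frozen=True)
class CatalogueEntry:
    transcript_id: str
    provenance: str        # annotated | known | novel
    subtype: str           # lincRNA | ilncRNA
    model: TranscriptModel


@dataclass
class LncCatalogue:
    entries: list[CatalogueEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.transcript_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids in catalogue")

    def subset(self, provenance: str | None = None,
               subtype: str | None = None) -> list[CatalogueEntry]:
        return [e for e in self.entries
                if (provenance is None or e.provenance == provenance)
                and (subtype is None or e.subtype == subtype)]

    @property
    def ids(self) -> set[str]:
        return {e.transcript_id for e in self.entries}


@dataclass
class PipelineConfig:
    """All cascade thresholds; defaults follow the published filter
    criteria (length > 200 nt, mono-exon cap 10 kb, FPKM >= 1 in >= 2
    samples, E < 1e-5, >= 3 coding votes, ORF > 300 aa, < 1 kb gene
    distance)."""

    min_length: int = 200
    max_monoexon_length: int = 10_000
    min_fpkm: float = 1.0
    min_expressed_samples: int = 2
    min_votes: int = 3
    max_orf_aa: int = 300
    min_gene_distance: int = 1_000
    repeat_min_overlap: int = 1
    orf_fraction_threshold: float = 0.5
    fickett_threshold: float = FICKETT_NONCODING_BOUND
    hexamer_threshold: float = 0.0
    search: SearchParams = field(default_factory=SearchParams)


def _repeat_overlap_bases(model: TranscriptModel,
                          repeats_by_chrom: dict[str, list[GenomicInterval]],
                          ) -> int:
    total = 0
    for rep in repeats_by_chrom.get(model.chrom, ()):
        for exon in model.exons:
            total += exon.overlap_length(rep)
    return total


def _coding_region(seq: str, orf) -> str:
    """Region the positional scorers evaluate: the longest complete ORF
    when it is >= 200 nt, else the whole transcript (TESTCODE is a
    windowed statistic; scoring the candidate coding region is standard
    practice)."""
    if orf.nt_length >= 200:
        return seq[orf.start:orf.start + orf.nt_length]
    return seq


def train_models_from_reference(reference: list[TranscriptModel],
                                genome: dict[str, str],
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Hexamer coding/noncoding models estimated from the reference
    annotation itself: coding from the longest ORFs of protein-coding
    transcripts, noncoding from annotated lncRNA transcripts (falling
    back to reference mononucleotide background if none exist)."""
    coding_seqs = []
    noncoding_seqs = []
    for tx in reference:
        seq = tx.sequence or extract_sequence(tx, genome)
        if tx.biotype == BIOTYPE_PROTEIN_CODING:
            orf = find_longest_orf(seq)
            if orf.nt_length >= 300:
                coding_seqs.append(seq[orf.start:orf.start + orf.nt_length])
        elif tx.biotype == BIOTYPE_ANNOTATED_LNCRNA:
            noncoding_seqs.append(seq)
    if not coding_seqs:
        raise ValueError("reference has no protein-coding transcripts with "
                         "ORFs to train the coding hexamer model")
    if not noncoding_seqs:
        logger.warning("no annotated lncRNAs in reference; noncoding "
                       "hexamer model falls back to uniform")
        noncoding_model = np.full(4096, 1.0 / 4096)
    else:
        noncoding_model = train_hexamer_model(noncoding_seqs)
    return train_hexamer_model(coding_seqs), noncoding_model


def run_discovery(assembled: list[TranscriptModel],
                  reference: list[TranscriptModel],
                  genome: dict[str, str],
                  repeats: list[GenomicInterval],
                  expression: ExpressionMatrix,
                  known_lnc_db: dict[str, str],
                  exclusion_dbs: dict[str, dict[str, str] | list[HitRecord]],
                  score_tables: pd.DataFrame | None = None,
                  config: PipelineConfig | None = None,
                  ) -> tuple[LncCatalogue, dict[str, FilterTrace]]:
    """Run the full discovery cascade; returns the catalogue and one
    :class:`FilterTrace` per input transcript.

    ``exclusion_dbs`` maps database name to either a sequence dict
    (searched with the built-in homology search) or a pre-computed hit
    list (externally produced blast-tabular results).
    ``score_tables`` optionally adds external per-tool coding scores
    (one column per tool, indexed by transcript id).
    """
    cfg = config or PipelineConfig()
    ref_index = ReferenceIndex(reference)
    coding_model, noncoding_model = train_models_from_reference(
        reference, genome)

    repeats_by_chrom: dict[str, list[GenomicInterval]] = {}
    for rep in repeats:
        repeats_by_chrom.setdefault(rep.chrom, []).append(rep)

    traces: dict[str, FilterTrace] = {}
    entries: list[CatalogueEntry] = []
    # ---- stage 1: classification ----------------------------------------
    survivors: list[tuple[TranscriptModel, str]] = []   # (model, class code)
    for model in assembled:
        trace = FilterTrace(model.transcript_id)
        traces[model.transcript_id] = trace
        if model.sequence is None:
            model.sequence = extract_sequence(model, genome)
        code = assign_class_code(model, ref_index)
        if code.code == CODE_MATCH:
            ref_tx = next(t for t in ref_index.transcripts
                          if t.transcript_id == code.matched_reference_id)
            trace.add(STAGE_CLASS_CODE, code.code, False)
            if ref_tx.biotype == BIOTYPE_ANNOTATED_LNCRNA:
                trace.terminal_category = TERM_ANNOTATED_LNC
                host = [g for g in ref_index.overlapping_genes(model.interval)
                        if g.biotype == BIOTYPE_PROTEIN_CODING
                        and g.interval.contains(model.interval)]
                entries.append(CatalogueEntry(
                    model.transcript_id, PROV_ANNOTATED,
                    SUBTYPE_ILNCRNA if host else SUBTYPE_LINCRNA, model))
            else:
                trace.terminal_category = TERM_ANNOTATED_MRNA
            continue
        if code.code == CODE_OTHER:
            trace.add(STAGE_CLASS_CODE, code.code, False)
            trace.terminal_category = TERM_OTHER_OVERLAP
            continue
        trace.add(STAGE_CLASS_CODE, code.code, True)
        survivors.append((model, code.code))

    # ---- stage 2: known-lncRNA catalogue ---------------------------------
    queries = {m.transcript_id: m.sequence for m, _ in survivors}
    known_hits = best_hits(homology_search(queries, known_lnc_db, cfg.search)
                           ) if known_lnc_db and queries else {}
    remaining: list[tuple[TranscriptModel, str]] = []
    for model, code in survivors:
        hit = known_hits.get(model.transcript_id)
        if hit is not None:
            traces[model.transcript_id].add(
                STAGE_KNOWN, f"{hit.subject_id}:E={hit.evalue:.3g}", False)
            subtype = subtype_lncrna(code)
            traces[model.transcript_id].terminal_category = (
                TERM_KNOWN_LINC if subtype == SUBTYPE_LINCRNA
                else TERM_KNOWN_ILNC)
            entries.append(CatalogueEntry(model.transcript_id, PROV_KNOWN,
                                          subtype, model))
        else:
            traces[model.transcript_id].add(STAGE_KNOWN, "no_hit", True)
            remaining.append((model, code))
    survivors = remaining

    # ---- stage 7 preparation: exclusion hits (computed lazily per db) ----
    def exclusion_hit(model: TranscriptModel,
                      db_hits: dict[str, dict[str, HitRecord]]) -> str | None:
        for db_name in sorted(db_hits):
            hit = db_hits[db_name].get(model.transcript_id)
            if hit is not None:
                return f"{db_name}:{hit.subject_id}:E={hit.evalue:.3g}"
        return None

    # sequence stages ------------------------------------------------------
    stage6_pool: list[tuple[TranscriptModel, str]] = []
    for model, code in survivors:
        trace = traces[model.transcript_id]
        length = model.length
        if length <= cfg.min_length:
            trace.add(STAGE_MIN_LENGTH, length, False)
            continue
        trace.add(STAGE_MIN_LENGTH, length, True)
        if model.exon_count == 1 and length > cfg.max_monoexon_length:
            trace.add(STAGE_MONOEXON, length, False)
            continue
        trace.add(STAGE_MONOEXON, length, True)
        overlap = _repeat_overlap_bases(model, repeats_by_chrom)
        if overlap >= cfg.repeat_min_overlap:
            trace.add(STAGE_REPEAT, overlap, False)
            continue
        trace.add(STAGE_REPEAT, overlap, True)
        stage6_pool.append((model, code))

    # ---- stage 6: expression --------------------------------------------
    stage7_pool: list[tuple[TranscriptModel, str]] = []
    values = expression.values
    for model, code in stage6_pool:
        trace = traces[model.transcript_id]
        tid = model.transcript_id
        if tid not in values.index:
            logger.warning("transcript %s absent from expression matrix", tid)
            trace.add(STAGE_EXPRESSION, "absent", False)
            continue
        n_expressed = int((values.loc[tid] >= cfg.min_fpkm).sum())
        if n_expressed < cfg.min_expressed_samples:
            trace.add(STAGE_EXPRESSION, n_expressed, False)
            continue
        trace.add(STAGE_EXPRESSION, n_expressed, True)
        stage7_pool.append((model, code))

    # ---- stage 7: exclusion databases -----------------------------------
    queries = {m.transcript_id: m.sequence for m, _ in stage7_pool}
    db_hits: dict[str, dict[str, HitRecord]] = {}
    for db_name, db in exclusion_dbs.items():
        if isinstance(db, dict):
            db_hits[db_name] = (best_hits(homology_search(queries, db,
                                                          cfg.search))
                                if queries and db else {})
        else:
            db_hits[db_name] = best_hits(
                [h for h in db
                 if h.evalue < cfg.search.evalue_cutoff
                 and h.query_id in queries])
    stage8_pool: list[tuple[TranscriptModel, str]] = []
    for model, code in stage7_pool:
        trace = traces[model.transcript_id]
        metric = exclusion_hit(model, db_hits)
        if metric is not None:
            trace.add(STAGE_EXCLUSION, metric, False)
            continue
        trace.add(STAGE_EXCLUSION, "no_hit", True)
        stage8_pool.append((model, code))

    # ---- stages 8-10: coding vote, ORF length, gene distance -------------
    for model, code in stage8_pool:
        trace = traces[model.transcript_id]
        seq = model.sequence
        orf = find_longest_orf(seq, include_reverse=(model.strand == "."))
        region = _coding_region(seq, orf)
        scores: dict[str, float | bool] = {
            "orf_fraction": orf_fraction(seq, orf),
            "fickett": fickett_score(region) if len(region) >= 200 else 0.0,
            "hexamer": hexamer_score(region, coding_model, noncoding_model),
        }
        if score_tables is not None and model.transcript_id in score_tables.index:
            for tool in score_tables.columns:
                value = score_tables.loc[model.transcript_id, tool]
                if pd.notna(value):
                    scores[tool] = value
        verdict = vote_coding(scores, cfg.min_votes, thresholds={
            "orf_fraction": cfg.orf_fraction_threshold,
            "fickett": cfg.fickett_threshold,
            "hexamer": cfg.hexamer_threshold,
        })
        if verdict.is_coding:
            trace.add(STAGE_CODING_VOTE, verdict.votes, False)
            continue
        trace.add(STAGE_CODING_VOTE, verdict.votes, True)
        if orf.aa_length > cfg.max_orf_aa:
            trace.add(STAGE_ORF, orf.aa_length, False)
            continue
        trace.add(STAGE_ORF, orf.aa_length, True)
        if code == CODE_INTERGENIC:
            report = nearest_protein_coding(model, ref_index,
                                            cfg.min_gene_distance)
            dists = [d for d in (report.left_distance, report.right_distance)
                     if d is not None]
            min_dist = min(dists) if dists else None
            if min_dist is not None and min_dist < cfg.min_gene_distance:
                trace.add(STAGE_DISTANCE, min_dist, False)
                continue
            trace.add(STAGE_DISTANCE,
                      min_dist if min_dist is not None else "none_in_window",
                      True)
        subtype = subtype_lncrna(code)
        trace.terminal_category = (TERM_NOVEL_LINC
                                   if subtype == SUBTYPE_LINCRNA
                                   else TERM_NOVEL_ILNC)
        entries.append(CatalogueEntry(model.transcript_id, PROV_NOVEL,
                                      subtype, model))

    return LncCatalogue(entries), traces


# --------------------------------------------------------------------------
# characterization reports
# --------------------------------------------------------------------------

_CLASS_ORDER = ("annotated_lncRNA", "known_lincRNA", "known_ilncRNA",
                "novel_lincRNA", "novel_ilncRNA", "mRNA")


def _class_of(entry: CatalogueEntry) -> str:
    if entry.provenance == PROV_ANNOTATED:
        return "annotated_lncRNA"
    return f"{entry.provenance}_{entry.subtype}"


def characterize_catalogue(catalogue: LncCatalogue,
                           expression: ExpressionMatrix,
                           mrnas: list[TranscriptModel] = (),
                           ) -> pd.DataFrame:
    """Per-class summary: mean/median GC%, spliced length, exon count and
    mean FPKM, plus (for novel lncRNAs) the fraction with <= 2 exons.

    Empty classes are reported with zero counts rather than dropped.
    """
    groups: dict[str, list[TranscriptModel]] = {c: [] for c in _CLASS_ORDER}
    for entry in catalogue.entries:
        groups[_class_of(entry)].append(entry.model)
    groups["mRNA"] = list(mrnas)
    rows = []
    values = expression.values
    for cls in _CLASS_ORDER:
        models = groups[cls]
        if not models:
            rows.append({"class": cls, "n": 0, "mean_gc": 0.0,
                         "median_gc": 0.0, "mean_length": 0.0,
                         "median_length": 0.0, "mean_exons": 0.0,
                         "mean_fpkm": 0.0, "fraction_le2_exons": 0.0})
            continue
        gcs = [m.gc_content * 100 for m in models]
        lengths = [m.length for m in models]
        exons = [m.exon_count for m in models]
        fpkms = [float(values.loc[m.transcript_id].mean())
                 for m in models if m.transcript_id in values.index]
        rows.append({
            "class": cls, "n": len(models),
            "mean_gc": float(np.mean(gcs)),
            "median_gc": float(np.median(gcs)),
            "mean_length": float(np.mean(lengths)),
            "median_length": float(np.median(lengths)),
            "mean_exons": float(np.mean(exons)),
            "mean_fpkm": float(np.mean(fpkms)) if fpkms else 0.0,
            "fraction_le2_exons": float(np.mean([e <= 2 for e in exons])),
        })
    return pd.DataFrame(rows).set_index("class")


def chromosome_distribution(catalogue: LncCatalogue) -> pd.DataFrame:
    """Counts of catalogue entries per chromosome per subtype (the
    tabular stand-in for a genome-wide density plot)."""
    rows: dict[tuple[str, str], int] = {}
    for entry in catalogue.entries:
        key = (entry.model.chrom, entry.subtype)
        rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["chrom", "subtype", "count"])
    df = pd.DataFrame([{"chrom": c, "subtype": s, "count": n}
                       for (c, s), n in sorted(rows.items())])
    return df
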