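"""Deterministic synthetic-world generator with complete planted truth.

The generator emits a miniature liver-transcriptome study: a random
genome, a reference annotation (protein-coding and lncRNA genes), an
"assembled" transcript set mixing annotated mRNAs/lncRNAs, catalogued
known lncRNAs, true novel lincRNAs/ilncRNAs and one family of decoys per
cascade filter, plus expression with planted differential expression and
lncRNA–mRNA co-expression, feed-efficiency QTL intervals, ortholog/
synteny structure across two foreign species, foreign lncRNA catalogues,
exclusion databases and a PPI graph with planted dense modules.

Every planted feature is recorded in a :class:`TruthTable` so each
downstream stage has an acceptance surface.  The same seed always yields
a byte-identical world.

Layout strategy: each chromosome is a left-to-right concatenation of
gene bodies and intergenic gaps; every gap carries at most one planted
intergenic feature with generous margins, so planted truth relations
(nearest neighbours, QTL containment, flanking-gene pairs) are exact by
construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io import (
    write_bed,
    write_fasta,
    write_gmt,
    write_gtf,
    write_position_table,
)
from .models import GeneSet, GenomicInterval, TranscriptModel
from .models import (
    BIOTYPE_ANNOTATED_LNCRNA,
    BIOTYPE_PROTEIN_CODING,
    BIOTYPE_UNKNOWN,
)
from .qtl import QTLRecord, write_qtl_table
from .synteny import write_ortholog_map

# --------------------------------------------------------------------------
# truth categories
# --------------------------------------------------------------------------

CAT_ANNOTATED_MRNA = "annotated_mRNA"
CAT_ANNOTATED_LNC = "annotated_lncRNA"
CAT_KNOWN_LINC = "known_lincRNA"
CAT_KNOWN_ILNC = "known_ilncRNA"
CAT_NOVEL_LINC = "novel_lincRNA"
CAT_NOVEL_ILNC = "novel_ilncRNA"

DECOY_MONOEXON = "decoy_monoexon_length"
DECOY_REPEAT = "decoy_repeat_overlap"
DECOY_LOW_EXPR = "decoy_low_expression"
DECOY_EXCLUSION = "decoy_exclusion_hit"
DECOY_CODING_VOTE = "decoy_coding_vote"
DECOY_LONG_ORF = "decoy_long_orf"
DECOY_NEAR_GENE = "decoy_near_gene"

DECOY_CATEGORIES = (DECOY_MONOEXON, DECOY_REPEAT, DECOY_LOW_EXPR,
                    DECOY_EXCLUSION, DECOY_CODING_VOTE, DECOY_LONG_ORF,
                    DECOY_NEAR_GENE)

#: cascade stage (see lncquarry.pipeline) each decoy family must fail at
DECOY_STAGE = {
    DECOY_MONOEXON: "monoexon_length",
    DECOY_REPEAT: "repeat_overlap",
    DECOY_LOW_EXPR: "expression",
    DECOY_EXCLUSION: "exclusion_db",
    DECOY_CODING_VOTE: "coding_vote",
    DECOY_LONG_ORF: "orf_length",
    DECOY_NEAR_GENE: "gene_distance",
}

SPECIES = ("human", "cow")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    Length/GC/exon targets follow the real catalogue contrasts: novel
    lncRNAs average ~733 nt, ~42% GC and 1–2 exons, mRNAs ~3.2 kb spliced
    length, ~50% GC and several exons.
    """

    seed: int = 17
    n_chromosomes: int = 3
    n_annotated_mrna: int = 30
    n_annotated_lnc: int = 10
    n_known_linc: int = 10
    n_known_ilnc: int = 5
    n_novel_linc: int = 50
    n_novel_ilnc: int = 15
    decoys_per_stage: int = 5
    samples_per_group: int = 8
    paper_design: bool = False          # 2 pooled samples per breed
    # sequence composition
    lnc_len_mean: float = 733.0
    lnc_len_sigma: float = 0.45
    lnc_len_min: int = 203
    lnc_len_max: int = 3000
    lnc_gc: float = 0.42
    utr_gc: float = 0.48
    background_gc: float = 0.45
    mrna_orf_aa_min: int = 350
    mrna_orf_aa_max: int = 1000
    mrna_exon_min: int = 4
    mrna_exon_max: int = 8
    intron_len_min: int = 400
    intron_len_max: int = 1500
    # expression
    noise_sd_log: float = 0.25
    de_fold_min: float = 3.0
    de_fold_max: float = 6.0
    n_de_known_linc: int = 5
    n_de_novel_linc: int = 3
    n_de_mrna: int = 6
    n_trans_pairs: int = 10
    trans_pair_r: float = 0.99
    # annotation extras
    n_qtl_linc_targets: int = 6
    n_qtl_ilnc_targets: int = 2
    n_qtl_background: int = 4
    n_syntenic: int = 20
    n_synteny_negatives: int = 6
    n_synteny_split: int = 2
    n_conserved: int = 6
    n_ppi_modules: int = 2
    ppi_module_size: int = 6
    n_ppi_background_edges: int = 150

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                if name != "seed" and value < 0:
                    raise ValueError(f"config field {name} must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    @property
    def samples_each(self) -> int:
        return 2 if self.paper_design else self.samples_per_group


@dataclass
class TruthTable:
    """Complete planted ground truth of a synthetic world."""

    category: dict[str, str] = field(default_factory=dict)
    de: dict[str, tuple[str, float]] = field(default_factory=dict)
    trans_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    syntenic: dict[str, dict[str, str]] = field(default_factory=dict)
    conserved: dict[str, list[str]] = field(default_factory=dict)
    qtl_members: dict[str, list[str]] = field(default_factory=dict)
    modules: list[list[str]] = field(default_factory=list)

    def ids_in_category(self, *categories: str) -> list[str]:
        return [tid for tid, cat in self.category.items()
                if cat in categories]

    @property
    def novel_ids(self) -> set[str]:
        return set(self.ids_in_category(CAT_NOVEL_LINC, CAT_NOVEL_ILNC))


@dataclass
class SyntheticWorld:
    config: GeneratorConfig
    genome: dict[str, str]
    reference: list[TranscriptModel]
    assembled: list[TranscriptModel]
    repeats: list[GenomicInterval]
    expression: ExpressionMatrix
    qtls: list[QTLRecord]
    ortholog_map: dict[str, dict[str, str]]
    foreign_genes: dict[str, dict[str, GenomicInterval]]
    foreign_lnc_positions: dict[str, dict[str, GenomicInterval]]
    foreign_lnc_seqs: dict[str, dict[str, str]]
    known_lnc_db: dict[str, str]
    exclusion_dbs: dict[str, dict[str, str]]
    ppi_edges: list[tuple[str, str, float]]
    gene_sets: list[GeneSet]
    truth: TruthTable


# --------------------------------------------------------------------------
# sequence samplers
# --------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")

# positional base probabilities of the synthetic "coding" codon model
# (order A, C, G, T per codon position); designed to give coding ORFs
# strong positional asymmetry and ~50% GC
_CODON_POS_P = (
    (0.32, 0.21, 0.315, 0.155),
    (0.28, 0.26, 0.24, 0.22),
    (0.23, 0.32, 0.18, 0.27),
)
_STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _coding_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Codons from the positionally biased model, stop codons excluded."""
    out = []
    # draw in batches, rejecting stops
    while len(out) < n_codons:
        need = n_codons - len(out) + 8
        cols = [rng.choice(4, size=need, p=np.array(p)) for p in _CODON_POS_P]
        arr = np.stack(cols, axis=1)
        for row in arr:
            codon = _BASES[row].tobytes().decode()
            if codon not in _STOP_CODONS:
                out.append(codon)
                if len(out) == n_codons:
                    break
    return "".join(out)


def _uniform_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free codons with uniform base composition (no coding bias)."""
    out = []
    while len(out) < n_codons:
        need = n_codons - len(out) + 8
        arr = rng.integers(0, 4, size=(need, 3))
        for row in arr:
            codon = _BASES[row].tobytes().decode()
            if codon not in _STOP_CODONS:
                out.append(codon)
                if len(out) == n_codons:
                    break
    return "".join(out)


def _orf(rng: np.random.Generator, aa_len: int, coding_bias: bool) -> str:
    """Complete ORF: ATG + (aa_len - 1) body codons + stop."""
    body = (_coding_codons if coding_bias else _uniform_codons)(rng, aa_len - 1)
    stop = ("TAA", "TGA", "TAG")[rng.integers(0, 3)]
    return START_CODON + body + stop


def _strip_long_orfs(seq: str, rng: np.random.Generator,
                     max_aa: int = 120) -> str:
    """Break any complete ORF longer than ``max_aa`` by an in-frame stop.

    Keeps planted non-coding sequences honestly non-coding without
    changing composition appreciably (random lncRNA-length sequences very
    rarely need it).
    """
    from .coding import find_longest_orf
    seq = list(seq)
    while True:
        rec = find_longest_orf("".join(seq))
        if rec.aa_length <= max_aa:
            return "".join(seq)
        mid = rec.start + 3 * (rec.aa_length // 2)
        stop = ("TAA", "TGA", "TAG")[rng.integers(0, 3)]
        seq[mid:mid + 3] = stop


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _split_lengths(rng: np.random.Generator, total: int, parts: int,
                   minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` pieces each >= ``minimum``."""
    if parts * minimum > total:
        raise ValueError(f"cannot split {total} into {parts} x >= {minimum}")
    extra = total - parts * minimum
    if parts == 1:
        return [total]
    weights = rng.dirichlet(np.ones(parts))
    sizes = [minimum + int(extra * w) for w in weights]
    sizes[-1] += total - sum(sizes)
    return sizes


# --------------------------------------------------------------------------
# expression simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprFeatureSpec:
    """One feature of the simulated FPKM matrix.

    ``de_fold``/``up_group``: samples of ``up_group`` get ``base_fpkm *
    de_fold``, all others ``base_fpkm`` (before multiplicative noise), so
    the expected group-mean ratio equals the planted fold exactly.
    """

    feature_id: str
    base_fpkm: float
    de_fold: float = 1.0
    up_group: str | None = None


def simulate_expression(specs: list[ExprFeatureSpec],
                        groups: dict[str, str],
                        noise_sd: float,
                        rng: np.random.Generator,
                        trans_pairs: list[tuple[str, str, float]] = (),
                        ) -> ExpressionMatrix:
    """Group-structured lognormal FPKM with planted folds and planted
    exact-correlation lncRNA-mRNA pairs.

    Noise is multiplicative lognormal (sd ``noise_sd`` on the log scale);
    ``noise_sd = 0`` gives the planted means exactly.  Trans pairs
    override both members' rows with a construction whose sample Pearson
    r equals the target exactly (up to non-negativity clipping).
    """
    from collections import Counter
    counts = Counter(groups.values())
    if len(counts) < 1 or min(counts.values()) < 2:
        raise ValueError("need >= 2 samples in every group")
    samples = list(groups)
    n = len(samples)
    rows: dict[str, np.ndarray] = {}
    for spec in specs:
        mult = np.array([spec.de_fold if groups[s] == spec.up_group else 1.0
                         for s in samples])
        noise = (np.exp(rng.normal(0.0, noise_sd, size=n))
                 if noise_sd > 0 else np.ones(n))
        rows[spec.feature_id] = spec.base_fpkm * mult * noise
    for lnc_id, gene_id, r in trans_pairs:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        lnc = np.exp(rng.normal(1.4, 0.8, size=n))
        lc = lnc - lnc.mean()
        eps = rng.normal(0.0, 1.0, size=n)
        eps = eps - eps.mean()
        eps = eps - (eps @ lc) / (lc @ lc) * lc
        u1 = lc / np.linalg.norm(lc)
        u2 = eps / np.linalg.norm(eps)
        direction = r * u1 + np.sqrt(max(0.0, 1.0 - r * r)) * u2
        gene = 6.0 + 2.5 * np.sqrt(n - 1) * direction
        rows[lnc_id] = lnc
        rows[gene_id] = np.clip(gene, 0.05, None)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ExpressionMatrix(values, groups)


# --------------------------------------------------------------------------
# gene / lncRNA construction
# --------------------------------------------------------------------------

@dataclass
class _PlacedGene:
    gene_id: str
    tx: TranscriptModel
    spliced: str
    genomic: str
    host_interval: GenomicInterval | None


def _make_gene(rng: np.random.Generator, cfg: GeneratorConfig, gene_id: str,
               chrom: str, start: int,
               host_content: str | None = None) -> _PlacedGene:
    """One protein-coding gene: complete biased ORF flanked by UTRs,
    split over several exons; optionally embeds a hosted sequence in the
    middle intron (with 300 nt pads)."""
    aa = int(rng.integers(cfg.mrna_orf_aa_min, cfg.mrna_orf_aa_max + 1))
    orf = _orf(rng, aa, coding_bias=True)
    utr_total = int(len(orf) * rng.uniform(0.3, 0.6))
    utr5 = 80 + int(rng.integers(0, utr_total - 160 + 1))
    utr3 = utr_total - utr5
    spliced = (_random_seq(rng, utr5, cfg.utr_gc) + orf
               + _random_seq(rng, utr3, cfg.utr_gc))
    k = int(rng.integers(cfg.mrna_exon_min, cfg.mrna_exon_max + 1))
    exon_lens = _split_lengths(rng, len(spliced), k, 80)
    intron_lens = [int(rng.integers(cfg.intron_len_min,
                                    cfg.intron_len_max + 1))
                   for _ in range(k - 1)]
    host_idx = None
    if host_content is not None:
        host_idx = (k - 1) // 2      # interior intron
        intron_lens[host_idx] = len(host_content) + 600
    strand = "+" if rng.random() < 0.7 else "-"
    # transcript-order exon contents -> genomic order
    parts = []
    off = 0
    for length in exon_lens:
        parts.append(spliced[off:off + length])
        off += length
    if strand == "+":
        genomic_exons = parts
    else:
        genomic_exons = [_revcomp(p) for p in reversed(parts)]
        exon_lens = list(reversed(exon_lens))
    segments = []
    exon_ivs = []
    host_iv = None
    cur = start
    for i, content in enumerate(genomic_exons):
        segments.append(content)
        exon_ivs.append(GenomicInterval(chrom, cur, cur + len(content) - 1,
                                        strand))
        cur += len(content)
        if i < k - 1:
            ilen = intron_lens[i]
            if host_idx is not None and i == host_idx:
                intron = (_random_seq(rng, 300, cfg.background_gc)
                          + host_content
                          + _random_seq(rng, 300, cfg.background_gc))
                host_iv = GenomicInterval(chrom, cur + 300,
                                          cur + 300 + len(host_content) - 1)
            else:
                intron = _random_seq(rng, ilen, cfg.background_gc)
            segments.append(intron)
            cur += len(intron)
    genomic = "".join(segments)
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, exon_ivs,
                         BIOTYPE_PROTEIN_CODING)
    return _PlacedGene(gene_id, tx, spliced, genomic, host_iv)


def _lnc_length(rng: np.random.Generator, cfg: GeneratorConfig,
                max_len: int | None = None) -> int:
    mu = np.log(cfg.lnc_len_mean) - cfg.lnc_len_sigma ** 2 / 2
    length = int(np.exp(rng.normal(mu, cfg.lnc_len_sigma)))
    hi = min(cfg.lnc_len_max, max_len) if max_len else cfg.lnc_len_max
    return int(np.clip(length, cfg.lnc_len_min, hi))


def _lnc_sequence(rng: np.random.Generator, cfg: GeneratorConfig,
                  length: int) -> str:
    return _strip_long_orfs(_random_seq(rng, length, cfg.lnc_gc), rng)


def _place_intergenic(rng: np.random.Generator, chrom: str, start: int,
                      spliced: str, n_exons: int, strand: str,
                      intron_range: tuple[int, int] = (300, 800),
                      ) -> tuple[list[GenomicInterval], str]:
    """Lay a (possibly spliced) transcript down at ``start``; returns the
    exon intervals and the genomic sequence it occupies."""
    if n_exons == 1:
        genomic = spliced if strand != "-" else _revcomp(spliced)
        return ([GenomicInterval(chrom, start, start + len(spliced) - 1,
                                 strand)], genomic)
    exon_lens = _split_lengths(rng, len(spliced), n_exons, 80)
    parts = []
    off = 0
    for length in exon_lens:
        parts.append(spliced[off:off + length])
        off += length
    if strand == "-":
        genomic_exons = [_revcomp(p) for p in reversed(parts)]
    else:
        genomic_exons = parts
    segments = []
    ivs = []
    cur = start
    for i, content in enumerate(genomic_exons):
        segments.append(content)
        ivs.append(GenomicInterval(chrom, cur, cur + len(content) - 1,
                                   strand))
        cur += len(content)
        if i < n_exons - 1:
            gc_level = 0.45
            ilen = int(rng.integers(intron_range[0], intron_range[1] + 1))
            segments.append(_random_seq(rng, ilen, gc_level))
            cur += ilen
    return ivs, "".join(segments)


# --------------------------------------------------------------------------
# world generation
# --------------------------------------------------------------------------

_PAD = 2000


def generate_world(config: GeneratorConfig | None = None) -> SyntheticWorld:
    """Generate the full synthetic study deterministically from the seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTable()

    # ---- job lists -------------------------------------------------------
    gap_jobs: list[str] = (
        [CAT_NOVEL_LINC] * cfg.n_novel_linc
        + [CAT_KNOWN_LINC] * cfg.n_known_linc
        + [CAT_ANNOTATED_LNC] * cfg.n_annotated_lnc
        + [d for d in DECOY_CATEGORIES for _ in range(cfg.decoys_per_stage)]
        + ["empty"] * (cfg.n_qtl_background + 2)
    )
    order = rng.permutation(len(gap_jobs))
    gap_jobs = [gap_jobs[i] for i in order]
    host_jobs: list[str] = ([CAT_NOVEL_ILNC] * cfg.n_novel_ilnc
                            + [CAT_KNOWN_ILNC] * cfg.n_known_ilnc)
    host_jobs = [host_jobs[i] for i in rng.permutation(len(host_jobs))]

    per_chrom_jobs = [gap_jobs[c::cfg.n_chromosomes]
                      for c in range(cfg.n_chromosomes)]
    n_genes_total = sum(len(j) + 1 for j in per_chrom_jobs)
    if len(host_jobs) > n_genes_total:
        raise ValueError(
            f"requested {len(host_jobs)} intronic lncRNAs but only "
            f"{n_genes_total} host genes are available; increase counts of "
            f"intergenic features or chromosomes")
    # spread host assignments over gene slots (collision-free)
    host_gene_idx: dict[int, str] = {}
    for i, job in enumerate(host_jobs):
        idx = int(round(i * (n_genes_total - 1) / max(1, len(host_jobs))))
        while idx in host_gene_idx:
            idx = (idx + 1) % n_genes_total
        host_gene_idx[idx] = job

    genome: dict[str, str] = {}
    reference: list[TranscriptModel] = []
    assembled: list[TranscriptModel] = []
    repeats: list[GenomicInterval] = []
    placed_genes: list[_PlacedGene] = []
    empty_gaps: list[GenomicInterval] = []
    #: per intergenic feature: dict with tid, category, flanks
    gap_features: list[dict] = []
    ilnc_features: list[dict] = []
    protein_fragments: dict[str, str] = {
        f"PROT{i:03d}": _coding_codons(rng, 134)
        for i in range(max(5, cfg.decoys_per_stage) + 5)}
    frag_cycle = sorted(protein_fragments)

    tid_counter = 0
    gene_counter = 0
    lncg_counter = 0
    frag_used = 0

    def next_tid() -> str:
        nonlocal tid_counter
        tid_counter += 1
        return f"MSTRG.{tid_counter}.1"

    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        parts: list[str] = [_random_seq(rng, _PAD, cfg.background_gc)]
        pos = _PAD + 1
        # one background repeat interval inside the left pad
        repeats.append(GenomicInterval(chrom, 500, 699))
        jobs = per_chrom_jobs[c]

        def place_gene() -> _PlacedGene:
            nonlocal pos, gene_counter
            gene_id = f"G{gene_counter:04d}"
            host_job = host_gene_idx.get(gene_counter)
            gene_counter += 1
            host_content = None
            hosted: dict | None = None
            if host_job is not None:
                length = _lnc_length(rng, cfg, max_len=1800)
                seq = _lnc_sequence(rng, cfg, length)
                strand = "+" if rng.random() < 0.5 else "-"
                host_content = seq if strand == "+" else _revcomp(seq)
                hosted = {"category": host_job, "spliced": seq,
                          "strand": strand}
            gene = _make_gene(rng, cfg, gene_id, chrom, pos, host_content)
            parts.append(gene.genomic)
            pos += len(gene.genomic)
            reference.append(gene.tx)
            placed_genes.append(gene)
            if hosted is not None:
                tid = next_tid()
                model = TranscriptModel(
                    tid, f"XLOC_{tid}",
                    [GenomicInterval(chrom, gene.host_interval.start,
                                     gene.host_interval.end,
                                     hosted["strand"])],
                    BIOTYPE_UNKNOWN, hosted["spliced"])
                assembled.append(model)
                truth.category[tid] = hosted["category"]
                ilnc_features.append({"tid": tid, "category":
                                      hosted["category"], "model": model,
                                      "host_gene": gene.gene_id})
            return gene

        prev_gene = place_gene()
        for job in jobs:
            if job == "empty":
                glen = int(rng.integers(7000, 9001))
                parts.append(_random_seq(rng, glen, cfg.background_gc))
                empty_gaps.append(GenomicInterval(chrom, pos, pos + glen - 1))
                pos += glen
                prev_gene = place_gene()
                continue
            # build the feature's spliced sequence / exon plan
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = 1
            category = job
            if job == CAT_NOVEL_LINC:
                length = _lnc_length(rng, cfg)
                spliced = _lnc_sequence(rng, cfg, length)
                n_exons = 1 if rng.random() < 0.75 else 2
            elif job == CAT_KNOWN_LINC:
                length = _lnc_length(rng, cfg)
                spliced = _lnc_sequence(rng, cfg, length)
                n_exons = 2
            elif job == CAT_ANNOTATED_LNC:
                length = _lnc_length(rng, cfg)
                spliced = _lnc_sequence(rng, cfg, length)
                n_exons = int(rng.integers(1, 4))
            elif job == DECOY_MONOEXON:
                length = int(rng.integers(10500, 12001))
                spliced = _lnc_sequence(rng, cfg, length)
            elif job == DECOY_REPEAT:
                length = int(rng.integers(500, 801))
                spliced = _lnc_sequence(rng, cfg, length)
            elif job == DECOY_LOW_EXPR:
                spliced = _lnc_sequence(rng, cfg, _lnc_length(rng, cfg))
            elif job == DECOY_EXCLUSION:
                frag = protein_fragments[frag_cycle[frag_used
                                                    % len(frag_cycle)]]
                frag_used += 1
                spliced = (_lnc_sequence(rng, cfg, 200) + frag
                           + _lnc_sequence(rng, cfg, 200))
            elif job == DECOY_CODING_VOTE:
                spliced = (_random_seq(rng, 40, cfg.utr_gc)
                           + _orf(rng, 250, coding_bias=True)
                           + _random_seq(rng, 40, cfg.utr_gc))
            elif job == DECOY_LONG_ORF:
                left = _lnc_sequence(rng, cfg, int(rng.integers(650, 801)))
                right = _lnc_sequence(rng, cfg, int(rng.integers(650, 801)))
                spliced = left + _orf(rng, 340, coding_bias=False) + right
            elif job == DECOY_NEAR_GENE:
                spliced = _lnc_sequence(rng, cfg, _lnc_length(rng, cfg))
            else:  # pragma: no cover - job list is closed
                raise AssertionError(job)
            left_margin = (int(rng.integers(300, 701))
                           if job == DECOY_NEAR_GENE
                           else int(rng.integers(2000, 3001)))
            right_margin = int(rng.integers(2000, 3001))
            parts.append(_random_seq(rng, left_margin, cfg.background_gc))
            pos += left_margin
            exons, genomic = _place_intergenic(rng, chrom, pos, spliced,
                                               n_exons, strand)
            tid = next_tid()
            model = TranscriptModel(tid, f"XLOC_{tid}", exons,
                                    BIOTYPE_UNKNOWN, spliced)
            parts.append(genomic)
            pos += len(genomic)
            if job == DECOY_REPEAT:
                mid = model.interval.start + 200
                repeats.append(GenomicInterval(chrom, mid, mid + 199))
            if job == CAT_ANNOTATED_LNC:
                # also present in the reference annotation as a lncRNA gene
                lncg_counter += 1
                ref_gene = f"LG{lncg_counter:03d}"
                reference.append(TranscriptModel(f"{ref_gene}.t1", ref_gene,
                                                 exons,
                                                 BIOTYPE_ANNOTATED_LNCRNA))
            assembled.append(model)
            truth.category[tid] = category
            gap_features.append({"tid": tid, "category": category,
                                 "model": model,
                                 "left_gene": prev_gene.gene_id,
                                 "right_gene": None})
            parts.append(_random_seq(rng, right_margin, cfg.background_gc))
            pos += right_margin
            prev_gene = place_gene()
            gap_features[-1]["right_gene"] = prev_gene.gene_id
        parts.append(_random_seq(rng, _PAD, cfg.background_gc))
        genome[chrom] = "".join(parts)

    # ---- assembled copies of annotated mRNAs -----------------------------
    pc_genes = [g for g in placed_genes]
    mrna_pick = sorted(rng.choice(len(pc_genes),
                                  size=min(cfg.n_annotated_mrna,
                                           len(pc_genes)),
                                  replace=False).tolist())
    mrna_gene_ids = []
    for gi in mrna_pick:
        g = pc_genes[gi]
        tid = next_tid()
        assembled.append(TranscriptModel(tid, f"XLOC_{tid}",
                                         list(g.tx.exons), BIOTYPE_UNKNOWN,
                                         g.spliced))
        truth.category[tid] = CAT_ANNOTATED_MRNA
        mrna_gene_ids.append(g.gene_id)

    # ---- known-lncRNA catalogue and exclusion databases ------------------
    known_lnc_db: dict[str, str] = {}
    nonc = 1
    for feat in gap_features:
        if feat["category"] == CAT_KNOWN_LINC:
            known_lnc_db[f"NONCGGA{nonc:05d}"] = feat["model"].sequence
            nonc += 1
    for feat in ilnc_features:
        if feat["category"] == CAT_KNOWN_ILNC:
            known_lnc_db[f"NONCGGA{nonc:05d}"] = feat["model"].sequence
            nonc += 1
    for _ in range(5):   # catalogue entries absent from this genome
        known_lnc_db[f"NONCGGA{nonc:05d}"] = _random_seq(
            rng, int(rng.integers(400, 1200)), cfg.lnc_gc)
        nonc += 1
    exclusion_dbs = {
        "protein": dict(protein_fragments),
        "mirna": {f"MIR{i:03d}": _random_seq(rng, 90, 0.45)
                  for i in range(8)},
        "rfam": {f"RF{i:05d}": _random_seq(rng, 120, 0.5)
                 for i in range(8)},
    }

    # ---- expression ------------------------------------------------------
    group_names = ("native", "commercial")
    n_each = cfg.samples_each
    groups = {f"{g}_{i + 1}": g for g in group_names for i in range(n_each)}

    novel_linc_ids = truth.ids_in_category(CAT_NOVEL_LINC)
    known_linc_ids = truth.ids_in_category(CAT_KNOWN_LINC)
    low_expr_ids = set(truth.ids_in_category(DECOY_LOW_EXPR))

    de_known = [known_linc_ids[i] for i in
                rng.choice(len(known_linc_ids),
                           size=min(cfg.n_de_known_linc, len(known_linc_ids)),
                           replace=False)]
    de_novel = [novel_linc_ids[i] for i in
                rng.choice(len(novel_linc_ids),
                           size=min(cfg.n_de_novel_linc, len(novel_linc_ids)),
                           replace=False)]
    de_mrna = [mrna_gene_ids[i] for i in
               rng.choice(len(mrna_gene_ids),
                          size=min(cfg.n_de_mrna, len(mrna_gene_ids)),
                          replace=False)] if mrna_gene_ids else []
    de_features = {}
    for fid in de_known + de_novel + de_mrna:
        fold = float(rng.uniform(cfg.de_fold_min, cfg.de_fold_max))
        up = group_names[int(rng.integers(0, 2))]
        de_features[fid] = (up, fold)
        truth.de[fid] = (up, fold)

    pc_gene_ids = [g.gene_id for g in placed_genes]
    pair_lnc_pool = [t for t in novel_linc_ids + known_linc_ids
                     if t not in de_features]
    pair_gene_pool = [g for g in pc_gene_ids if g not in de_features]
    n_pairs = min(cfg.n_trans_pairs, len(pair_lnc_pool),
                  len(pair_gene_pool))
    pair_lncs = [pair_lnc_pool[i] for i in
                 rng.choice(len(pair_lnc_pool), size=n_pairs, replace=False)]
    pair_genes = [pair_gene_pool[i] for i in
                  rng.choice(len(pair_gene_pool), size=n_pairs,
                             replace=False)]
    trans_pairs = [(l, g, cfg.trans_pair_r)
                   for l, g in zip(pair_lncs, pair_genes)]
    truth.trans_pairs = list(trans_pairs)

    specs = []
    for model in assembled:
        tid = model.transcript_id
        if tid in low_expr_ids:
            base = float(rng.uniform(0.1, 0.5))
        else:
            base = float(np.clip(np.exp(rng.normal(1.2, 0.7)), 1.8, 60.0))
        up, fold = de_features.get(tid, (None, 1.0))
        specs.append(ExprFeatureSpec(tid, base, fold, up))
    for gid in pc_gene_ids:
        base = float(np.clip(np.exp(rng.normal(1.2, 0.7)), 0.3, 80.0))
        up, fold = de_features.get(gid, (None, 1.0))
        specs.append(ExprFeatureSpec(gid, base, fold, up))
    expression = simulate_expression(specs, groups, cfg.noise_sd_log, rng,
                                     trans_pairs)

    # ---- QTLs ------------------------------------------------------------
    qtls: list[QTLRecord] = []
    traits = ("Feed intake", "Residual feed intake", "Feed conversion ratio")
    qtl_n = 0

    def add_qtl(iv: GenomicInterval, trait: str) -> str:
        nonlocal qtl_n
        qtl_n += 1
        qid = f"QTL{64550 + qtl_n}"
        qtls.append(QTLRecord(qid, trait, iv))
        return qid

    linc_feats = [f for f in gap_features if f["category"] == CAT_NOVEL_LINC]
    linc_targets = [linc_feats[i] for i in
                    rng.choice(len(linc_feats),
                               size=min(cfg.n_qtl_linc_targets,
                                        len(linc_feats)), replace=False)]
    for rank, feat in enumerate(linc_targets):
        n_q = 3 if rank == 0 else (2 if rank == 1 else 1)
        iv = feat["model"].interval
        ids = []
        for _ in range(n_q):
            hw_l = int(rng.integers(800, 2001))
            hw_r = int(rng.integers(800, 2001))
            trait = traits[qtl_n % 2]
            ids.append(add_qtl(GenomicInterval(iv.chrom,
                                               max(1, iv.start - hw_l),
                                               iv.end + hw_r), trait))
        truth.qtl_members[feat["tid"]] = ids
    ilnc_pool = [f for f in ilnc_features
                 if f["category"] == CAT_NOVEL_ILNC]
    ilnc_targets = [ilnc_pool[i] for i in
                    rng.choice(len(ilnc_pool),
                               size=min(cfg.n_qtl_ilnc_targets,
                                        len(ilnc_pool)), replace=False)
                    ] if ilnc_pool else []
    for feat in ilnc_targets:
        iv = feat["model"].interval
        hw_l = int(rng.integers(200, 501))
        hw_r = int(rng.integers(200, 501))
        qid = add_qtl(GenomicInterval(iv.chrom, max(1, iv.start - hw_l),
                                      iv.end + hw_r), traits[qtl_n % 2])
        truth.qtl_members[feat["tid"]] = [qid]
    for gap in empty_gaps[:cfg.n_qtl_background]:
        center = (gap.start + gap.end) // 2
        hw = int(rng.integers(800, 1501))
        add_qtl(GenomicInterval(gap.chrom, center - hw, center + hw),
                traits[2])
    return _finish_world(cfg, rng, truth, genome, reference, assembled,
                         repeats, expression, qtls, known_lnc_db,
                         exclusion_dbs, gap_features, pc_gene_ids)


def _finish_world(cfg, rng, truth, genome, reference, assembled, repeats,
                  expression, qtls, known_lnc_db, exclusion_dbs,
                  gap_features, pc_gene_ids) -> SyntheticWorld:
    """Synteny structure, foreign catalogues, PPI graph and gene sets."""
    # ---- synteny ---------------------------------------------------------
    ortholog_map: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
    foreign_genes: dict[str, dict[str, GenomicInterval]] = {sp: {}
                                                            for sp in SPECIES}
    foreign_lnc_positions: dict[str, dict[str, GenomicInterval]] = {
        sp: {} for sp in SPECIES}
    foreign_lnc_seqs: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
    cursors = {sp: 10_000 for sp in SPECIES}
    lnc_counter = {sp: 0 for sp in SPECIES}
    prefix = {"human": "HS", "cow": "BT"}

    def foreign_gene_id(sp: str, chicken_gene: str) -> str:
        return f"{prefix[sp]}_{chicken_gene}"

    def new_foreign_lnc(sp: str, length: int, seq: str,
                        iv: GenomicInterval) -> str:
        lnc_counter[sp] += 1
        fid = f"{prefix[sp]}_LNC{lnc_counter[sp]:04d}"
        foreign_lnc_positions[sp][fid] = iv
        foreign_lnc_seqs[sp][fid] = seq
        return fid

    linc_feats = [f for f in gap_features
                  if f["category"] == CAT_NOVEL_LINC]
    used_flanks: set[str] = set()
    eligible: list[dict] = []
    for feat in linc_feats:
        if feat["left_gene"] in used_flanks or feat["right_gene"] in used_flanks:
            continue
        used_flanks.add(feat["left_gene"])
        used_flanks.add(feat["right_gene"])
        eligible.append(feat)

    n_syn = min(cfg.n_syntenic, len(eligible))
    syn_feats = eligible[:n_syn]
    rest = eligible[n_syn:]
    neg_feats = rest[:cfg.n_synteny_negatives]
    split_feats = rest[cfg.n_synteny_negatives:
                       cfg.n_synteny_negatives + cfg.n_synteny_split]
    conserved_feats = syn_feats[:min(cfg.n_conserved, len(syn_feats))]

    def species_for(i: int) -> tuple[str, ...]:
        if i < max(0, n_syn - 6):
            return SPECIES
        return ("human",) if i % 2 == 0 else ("cow",)

    for i, feat in enumerate(syn_feats):
        tid = feat["tid"]
        truth.syntenic[tid] = {}
        for sp in species_for(i):
            chrom = f"{sp}_chr1"
            cur = cursors[sp]
            x_id = foreign_gene_id(sp, feat["left_gene"])
            y_id = foreign_gene_id(sp, feat["right_gene"])
            foreign_genes[sp][x_id] = GenomicInterval(chrom, cur, cur + 999)
            if feat in conserved_feats:
                seq = feat["model"].sequence
            else:
                seq = _random_seq(rng, int(rng.integers(300, 801)),
                                  cfg.lnc_gc)
            liv = GenomicInterval(chrom, cur + 1500, cur + 1500 + len(seq) - 1)
            fid = new_foreign_lnc(sp, len(seq), seq, liv)
            foreign_genes[sp][y_id] = GenomicInterval(
                chrom, cur + 2000 + len(seq), cur + 2999 + len(seq))
            ortholog_map[sp][feat["left_gene"]] = x_id
            ortholog_map[sp][feat["right_gene"]] = y_id
            cursors[sp] = cur + 20_000 + len(seq)
            truth.syntenic[tid][sp] = fid
            if feat in conserved_feats:
                truth.conserved.setdefault(tid, []).append(sp)
    for feat in neg_feats:
        for sp in SPECIES:
            chrom = f"{sp}_chr1"
            cur = cursors[sp]
            x_id = foreign_gene_id(sp, feat["left_gene"])
            y_id = foreign_gene_id(sp, feat["right_gene"])
            foreign_genes[sp][x_id] = GenomicInterval(chrom, cur, cur + 999)
            foreign_genes[sp][y_id] = GenomicInterval(chrom, cur + 1300,
                                                      cur + 2299)
            ortholog_map[sp][feat["left_gene"]] = x_id
            ortholog_map[sp][feat["right_gene"]] = y_id
            cursors[sp] = cur + 20_000
    for feat in split_feats:
        for sp in SPECIES:
            cur = cursors[sp]
            x_id = foreign_gene_id(sp, feat["left_gene"])
            y_id = foreign_gene_id(sp, feat["right_gene"])
            foreign_genes[sp][x_id] = GenomicInterval(f"{sp}_chr1", cur,
                                                      cur + 999)
            foreign_genes[sp][y_id] = GenomicInterval(f"{sp}_chr2", cur,
                                                      cur + 999)
            ortholog_map[sp][feat["left_gene"]] = x_id
            ortholog_map[sp][feat["right_gene"]] = y_id
            cursors[sp] = cur + 20_000
    # decoy foreign lncRNAs far from any ortholog pair
    for sp in SPECIES:
        for _ in range(10):
            cur = cursors[sp]
            seq = _random_seq(rng, int(rng.integers(300, 801)), cfg.lnc_gc)
            new_foreign_lnc(sp, len(seq), seq,
                            GenomicInterval(f"{sp}_chr9", cur,
                                            cur + len(seq) - 1))
            cursors[sp] = cur + 5_000

    # ---- PPI graph with planted modules ----------------------------------
    ppi_edges: list[tuple[str, str, float]] = []
    module_nodes: list[list[str]] = []
    pool = sorted(pc_gene_ids)
    need = cfg.n_ppi_modules * cfg.ppi_module_size
    picked = [pool[i] for i in rng.choice(len(pool), size=min(need, len(pool)),
                                          replace=False)]
    for m in range(cfg.n_ppi_modules):
        nodes = sorted(picked[m * cfg.ppi_module_size:
                              (m + 1) * cfg.ppi_module_size])
        if len(nodes) < cfg.ppi_module_size:
            break
        module_nodes.append(nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                ppi_edges.append((nodes[i], nodes[j], 1.0))
    truth.modules = [list(m) for m in module_nodes]
    in_module = {n: k for k, nodes in enumerate(module_nodes) for n in nodes}
    seen_pairs = {frozenset((a, b)) for a, b, _ in ppi_edges}
    # background edges live outside the planted complexes; each module is
    # attached to the rest of the graph by exactly two boundary edges, so
    # planted complexes stay cohesive against the background
    outside = [n for n in pool if n not in in_module]
    guard = 0
    n_bg = 0
    while n_bg < cfg.n_ppi_background_edges and guard < 100_000 \
            and len(outside) > 1:
        guard += 1
        i, j = rng.integers(0, len(outside), size=2)
        a, b = outside[i], outside[j]
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        ppi_edges.append((a, b, float(rng.uniform(0.4, 1.0))))
        n_bg += 1
    for nodes in module_nodes:
        for k in range(min(2, len(outside))):
            a = nodes[int(rng.integers(0, len(nodes)))]
            b = outside[int(rng.integers(0, len(outside)))]
            key = frozenset((a, b))
            if key not in seen_pairs:
                seen_pairs.add(key)
                ppi_edges.append((a, b, float(rng.uniform(0.4, 1.0))))

    # ---- gene sets --------------------------------------------------------
    gene_sets: list[GeneSet] = []
    for k, nodes in enumerate(module_nodes):
        extras = [pool[i] for i in rng.choice(len(pool), size=2,
                                              replace=False)]
        gene_sets.append(GeneSet(f"SET_MODULE_{k + 1}",
                                 f"planted module {k + 1} neighbourhood",
                                 frozenset(nodes) | frozenset(extras)))
    for k in range(6):
        size = min(int(rng.integers(10, 21)), len(pool))
        members = [pool[i] for i in rng.choice(len(pool), size=size,
                                               replace=False)]
        gene_sets.append(GeneSet(f"SET_RAND_{k + 1}",
                                 f"random control set {k + 1}",
                                 frozenset(members)))

    return SyntheticWorld(
        config=cfg, genome=genome, reference=reference, assembled=assembled,
        repeats=repeats, expression=expression, qtls=qtls,
        ortholog_map=ortholog_map, foreign_genes=foreign_genes,
        foreign_lnc_positions=foreign_lnc_positions,
        foreign_lnc_seqs=foreign_lnc_seqs, known_lnc_db=known_lnc_db,
        exclusion_dbs=exclusion_dbs, ppi_edges=ppi_edges,
        gene_sets=gene_sets, truth=truth)


# --------------------------------------------------------------------------
# emission and checksums
# --------------------------------------------------------------------------

def emit_world(world: SyntheticWorld, directory: str | Path,
               ) -> dict[str, str]:
    """Write every world input to ``directory`` in the formats the
    readers in :mod:`lncquarry.io` understand; returns a manifest of
    file name -> SHA-256, also written to ``manifest.json``."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)

    write_fasta(world.genome, out / "genome.fa")
    write_gtf(world.reference, out / "reference.gtf")
    write_gtf(world.assembled, out / "assembled.gtf")
    write_bed(world.repeats, out / "repeats.bed")
    world.expression.to_tsv(out / "expression.tsv", out / "groups.tsv")
    write_qtl_table(world.qtls, out / "qtls.tsv")
    write_ortholog_map(world.ortholog_map, out / "orthologs.tsv")
    for sp in sorted(world.foreign_genes):
        write_position_table(world.foreign_genes[sp],
                             out / f"foreign_genes_{sp}.tsv")
        write_position_table(world.foreign_lnc_positions[sp],
                             out / f"foreign_lnc_{sp}.tsv")
        write_fasta(world.foreign_lnc_seqs[sp], out / f"foreign_lnc_{sp}.fa")
    write_fasta(world.known_lnc_db, out / "known_lnc.fa")
    for name in sorted(world.exclusion_dbs):
        write_fasta(world.exclusion_dbs[name], out / f"exclusion_{name}.fa")
    with open(out / "ppi.tsv", "w") as fh:
        for a, b, w in world.ppi_edges:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
    write_gmt(world.gene_sets, out / "gene_sets.gmt")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("transcript_id\tcategory\n")
        for tid in sorted(world.truth.category):
            fh.write(f"{tid}\t{world.truth.category[tid]}\n")
    extra = {
        "de": {k: list(v) for k, v in sorted(world.truth.de.items())},
        "trans_pairs": [list(t) for t in world.truth.trans_pairs],
        "syntenic": {k: dict(sorted(v.items()))
                     for k, v in sorted(world.truth.syntenic.items())},
        "conserved": {k: sorted(v)
                      for k, v in sorted(world.truth.conserved.items())},
        "qtl_members": {k: sorted(v)
                        for k, v in sorted(world.truth.qtl_members.items())},
        "modules": [sorted(m) for m in world.truth.modules],
    }
    with open(out / "truth_extra.json", "w") as fh:
        json.dump(extra, fh, indent=1, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(world.config), fh, indent=1, sort_keys=True)

    manifest: dict[str, str] = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def world_checksum(world: SyntheticWorld) -> str:
    """SHA-256 over the serialized world (its emitted files)."""
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        manifest = emit_world(world, tmp)
    digest = hashlib.sha256()
    for name in sorted(manifest):
        digest.update(f"{name}:{manifest[name]}\n".encode())
    return digest.hexdigest()


def read_truth_table(directory: str | Path) -> TruthTable:
    """Reconstruct the truth table from an emitted world directory."""
    out = Path(directory)
    truth = TruthTable()
    with open(out / "truth.tsv") as fh:
        next(fh)
        for line in fh:
            tid, cat = line.rstrip("\n").split("\t")
            truth.category[tid] = cat
    with open(out / "truth_extra.json") as fh:
        extra = json.load(fh)
    truth.de = {k: (v[0], float(v[1])) for k, v in extra["de"].items()}
    truth.trans_pairs = [(a, b, float(r))
                         for a, b, r in extra["trans_pairs"]]
    truth.syntenic = extra["syntenic"]
    truth.conserved = extra["conserved"]
    truth.qtl_members = extra["qtl_members"]
    truth.modules = extra["modules"]
    return truth
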