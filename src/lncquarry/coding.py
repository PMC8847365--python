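"""Coding-potential scoring and the built-in nucleotide homology search.

Three internal predictors are provided — longest complete ORF (and the
fraction of the transcript it covers), the classic Fickett TESTCODE
statistic, and an in-frame hexamer log-likelihood ratio — together with a
majority-vote rule over any mix of internal and externally supplied
per-tool scores.  The homology search is an ungapped seed-and-extend
scorer with Karlin–Altschul E-values, used by the exclusion filters and
the known-lncRNA / conservation lookups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .models import HitRecord

logger = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_ALPHABET = set("ACGTN")


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters "
                         f"{sorted(bad)}")


@dataclass(frozen=True)
class OrfRecord:
    """The longest complete (ATG...stop) open reading frame of a transcript.

    ``aa_length`` counts codons excluding the stop; ``nt_length`` includes
    the stop codon, so ``aa_length == nt_length // 3 - 1`` for complete
    ORFs.  ``aa_length == 0`` means no ATG->stop span exists.
    """

    frame: int
    start: int          # 0-based offset within the transcript
    nt_length: int
    aa_length: int
    has_start: bool
    has_stop: bool


_EMPTY_ORF = OrfRecord(0, 0, 0, 0, False, False)


def _scan_frames(seq: str) -> OrfRecord:
    best = _EMPTY_ORF
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if open_start is None:
                if codon == "ATG":        # codons containing N never match
                    open_start = pos
            elif codon in _STOPS:
                nt_len = pos + 3 - open_start
                aa_len = nt_len // 3 - 1
                if (aa_len, -open_start) > (best.aa_length, -best.start):
                    best = OrfRecord(frame, open_start, nt_len, aa_len,
                                     True, True)
                open_start = None
    return best


def find_longest_orf(seq: str, include_reverse: bool = False) -> OrfRecord:
    """Longest complete ORF over the 3 sense-strand frames.

    Ties are broken by smaller start offset.  ``include_reverse`` scans all
    six frames (used for unstranded transcripts); the record then refers to
    the reported orientation's coordinates.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    _check_alphabet(seq)
    best = _scan_frames(seq)
    if include_reverse:
        from .classify import reverse_complement
        rev = _scan_frames(reverse_complement(seq))
        if (rev.aa_length, -rev.start) > (best.aa_length, -best.start):
            best = rev
    return best


def orf_fraction(seq: str, orf: OrfRecord | None = None) -> float:
    """Fraction of the transcript covered by its longest complete ORF."""
    if orf is None:
        orf = find_longest_orf(seq)
    return orf.nt_length / len(seq)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------
# The published TESTCODE lookup tables: eight parameters (position
# asymmetry and content of each base) are binned and mapped to the
# probability of the bin in coding sequence, then combined by the
# published weights.  Scores above ~0.95 are the published "coding" call
# and below ~0.74 "non-coding".

_POSITION_BINS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_BINS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.58, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

#: published TESTCODE decision bounds: <= NONCODING_BOUND non-coding,
#: >= CODING_BOUND coding, in between "no opinion"
FICKETT_NONCODING_BOUND = 0.74
FICKETT_CODING_BOUND = 0.95


def _bin_lookup(value: float, bins: tuple[float, ...],
                probs: tuple[float, ...]) -> float:
    for threshold, prob in zip(bins, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Classic TESTCODE statistic; higher = more coding-like.

    Requires >= 200 nt (shorter candidates should already have been
    removed by the length filter).  Case-insensitive; N bases are ignored
    in the counts.
    """
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError("fickett_score requires >= 200 nt; apply the "
                         "length filter first")
    _check_alphabet(seq)
    total = 0.0
    n_counted = sum(seq.count(b) for b in "ACGT")
    for base in "ACGT":
        counts = [0, 0, 0]
        for phase in range(3):
            counts[phase] = seq[phase::3].count(base)
        position_value = max(counts) / (min(counts) + 1)
        total += (_bin_lookup(position_value, _POSITION_BINS,
                              _POSITION_PROB[base])
                  * _POSITION_WEIGHT[base])
        content = seq.count(base) / n_counted if n_counted else 0.0
        total += (_bin_lookup(content, _CONTENT_BINS, _CONTENT_PROB[base])
                  * _CONTENT_WEIGHT[base])
    return total


# ---------------------------------------------------------------------------
# Hexamer usage
# ---------------------------------------------------------------------------

HEXAMER_KEYS = 4096
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hexamer_index(hexamer: str) -> int | None:
    idx = 0
    for ch in hexamer:
        b = _BASE_INDEX.get(ch)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def train_hexamer_model(seqs: list[str] | dict[str, str],
                        pseudocount: float = 1.0) -> np.ndarray:
    """Smoothed in-frame hexamer frequency table (4096 entries) estimated
    from the given sequences, read in frame 0 with step 3."""
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive for smoothing")
    counts = np.full(HEXAMER_KEYS, pseudocount, dtype=float)
    for seq in seqs:
        seq = seq.upper()
        for pos in range(0, len(seq) - 5, 3):
            idx = _hexamer_index(seq[pos:pos + 6])
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def hexamer_score(seq: str, coding_model: np.ndarray,
                  noncoding_model: np.ndarray) -> float:
    """Mean over in-frame hexamers of log(coding/noncoding) frequency;
    positive = coding-like."""
    for name, model in (("coding", coding_model),
                        ("noncoding", noncoding_model)):
        model = np.asarray(model)
        if model.shape != (HEXAMER_KEYS,):
            raise ValueError(f"{name} model must have {HEXAMER_KEYS} entries")
        if np.any(model <= 0):
            raise ValueError(f"{name} model has zero entries; smooth it")
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    log_ratio = np.log(np.asarray(coding_model) / np.asarray(noncoding_model))
    values = []
    for pos in range(0, len(seq) - 5, 3):
        idx = _hexamer_index(seq[pos:pos + 6])
        if idx is not None:
            values.append(log_ratio[idx])
    if not values:
        raise ValueError("no scorable hexamers (all contain N)")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

#: per-scorer "coding" thresholds.  The five named external tools use the
#: published cutoffs; the three internal scorers use the documented
#: defaults (Fickett boundary = published non-coding bound).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "cpc2": 0.5,          # score > 0.5
    "cnci": 0.0,          # score > 0
    "cpat": 0.36,         # score > 0.36
    "plek": 0.0,          # score > 0
    "orf_fraction": 0.5,
    "fickett": FICKETT_NONCODING_BOUND,
    "hexamer": 0.0,
}

#: scorers whose value is already a boolean coding flag
FLAG_SCORERS = ("feelnc",)


@dataclass(frozen=True)
class CodingVerdict:
    scores: dict[str, float | bool]
    flags: dict[str, bool]
    votes: int
    min_votes: int
    is_coding: bool


def vote_coding(scores: dict[str, float | bool], min_votes: int = 3,
                thresholds: dict[str, float] | None = None) -> CodingVerdict:
    """Apply each scorer's threshold and call coding at >= ``min_votes``
    coding flags ("simultaneously considered coding by at least k tools").

    Raises if fewer scorers are available than ``min_votes``: a vote that
    cannot reach quorum must not silently pass transcripts.
    """
    if len(scores) < min_votes:
        raise ValueError(
            f"only {len(scores)} scorers available but min_votes={min_votes}")
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    flags: dict[str, bool] = {}
    for name, value in scores.items():
        if isinstance(value, bool) or name in FLAG_SCORERS:
            flags[name] = bool(value)
        else:
            if name not in thresholds:
                raise KeyError(f"no threshold registered for scorer {name!r}")
            flags[name] = value > thresholds[name]
    votes = sum(flags.values())
    return CodingVerdict(dict(scores), flags, votes, min_votes,
                         votes >= min_votes)


# ---------------------------------------------------------------------------
# Homology search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Ungapped search parameters with classic nucleotide Karlin–Altschul
    constants; ``evalue = m * n * 2 ** -bitscore``."""

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    lam: float = 1.33
    k_param: float = 0.621
    evalue_cutoff: float = 1e-5
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k_param <= 0:
            raise ValueError("lambda and K must be positive")
        if self.word_size < 4:
            raise ValueError("word size must be >= 4")

    def bitscore(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.k_param)) / math.log(2)

    def evalue(self, raw: int, search_space: float) -> float:
        return search_space * 2.0 ** (-self.bitscore(raw))


def _extend(query: str, subject: str, qpos: int, spos: int,
            params: SearchParams) -> tuple[int, int, int, int]:
    """Ungapped bidirectional X-drop extension of a seed.

    Returns (raw_score, q_start, alignment_length, n_matches).
    """
    k = params.word_size
    score = k * params.match
    matches = k
    # extend right
    best_r, run_r, run_m = 0, 0, 0
    i, j = qpos + k, spos + k
    cur = 0
    cur_m = 0
    while i < len(query) and j < len(subject):
        cur += params.match if query[i] == subject[j] else params.mismatch
        cur_m += 1 if query[i] == subject[j] else 0
        if cur > best_r:
            best_r, run_r, run_m = cur, i - (qpos + k) + 1, cur_m
        if cur < best_r - params.xdrop:
            break
        i += 1
        j += 1
    # extend left
    best_l, run_l, run_lm = 0, 0, 0
    i, j = qpos - 1, spos - 1
    cur = 0
    cur_m = 0
    while i >= 0 and j >= 0:
        cur += params.match if query[i] == subject[j] else params.mismatch
        cur_m += 1 if query[i] == subject[j] else 0
        if cur > best_l:
            best_l, run_l, run_lm = cur, qpos - i, cur_m
        if cur < best_l - params.xdrop:
            break
        i -= 1
        j -= 1
    raw = score + best_r + best_l
    aln_len = k + run_r + run_l
    n_match = matches + run_m + run_lm
    return raw, qpos - run_l, aln_len, n_match


def homology_search(queries: dict[str, str], subjects: dict[str, str],
                    params: SearchParams | None = None) -> list[HitRecord]:
    """Exact k-mer seeded, ungapped X-drop extended search.

    The search space is ``m * n`` with m the query length and n the total
    subject length.  The best hit per query–subject pair with
    ``E < evalue_cutoff`` is reported, sorted by (query, E-value).
    """
    params = params or SearchParams()
    if not subjects:
        raise ValueError("subject set must be non-empty")
    k = params.word_size
    shortest = min(len(s) for s in subjects.values())
    if k > shortest:
        raise ValueError(f"word size {k} larger than shortest subject "
                         f"({shortest} nt)")
    total_subject = sum(len(s) for s in subjects.values())

    index: dict[str, list[tuple[str, int]]] = {}
    for sid, sseq in subjects.items():
        for pos in range(len(sseq) - k + 1):
            index.setdefault(sseq[pos:pos + k], []).append((sid, pos))

    hits: list[HitRecord] = []
    for qid, qseq in queries.items():
        best: dict[str, tuple[int, int, int]] = {}   # sid -> (raw, len, match)
        seen_diag: dict[tuple[str, int], int] = {}   # (sid, diag) -> qend
        for qpos in range(len(qseq) - k + 1):
            for sid, spos in index.get(qseq[qpos:qpos + k], ()):
                diag = qpos - spos
                if seen_diag.get((sid, diag), -1) >= qpos:
                    continue
                raw, qstart, aln_len, n_match = _extend(
                    qseq, subjects[sid], qpos, spos, params)
                seen_diag[(sid, diag)] = qstart + aln_len - 1
                if raw > best.get(sid, (0, 0, 0))[0]:
                    best[sid] = (raw, aln_len, n_match)
        space = len(qseq) * total_subject
        for sid, (raw, aln_len, n_match) in best.items():
            evalue = params.evalue(raw, space)
            if evalue < params.evalue_cutoff:
                hits.append(HitRecord(qid, sid, 100.0 * n_match / aln_len,
                                      aln_len, params.bitscore(raw), evalue))
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits


def best_hits(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Best (lowest E) hit per query."""
    out: dict[str, HitRecord] = {}
    for h in hits:
        if h.query_id not in out or h.evalue < out[h.query_id].evalue:
            out[h.query_id] = h
    return out
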