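"""Cross-species conservation of lncRNAs: sequence homology against
foreign lncRNA catalogues, and positional (synteny) conservation.

A chicken lincRNA flanked by protein-coding genes X (upstream) and Y
(downstream) is called syntenic in a foreign species when a foreign
lncRNA lies strictly between the orthologs X' and Y' on one foreign
chromosome.  The test is orientation-agnostic: only the open interval
between the two ortholog gene bodies matters, and a foreign lncRNA
overlapping either gene body does not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ReferenceIndex, nearest_protein_coding
from .coding import SearchParams, homology_search
from .models import GenomicInterval, HitRecord, TranscriptModel

REASON_SYNTENIC = "syntenic"
REASON_NO_FLANKING = "no_flanking_pair"
REASON_NO_ORTHOLOGS = "no_orthologs"
REASON_SPLIT_PAIR = "split_pair"
REASON_OVERLAPPING = "overlapping_orthologs"
REASON_NO_FOREIGN_LNC = "no_foreign_lncRNA_between"


@dataclass(frozen=True)
class SyntenyCall:
    lnc_id: str
    species: str
    upstream_gene: str | None
    downstream_gene: str | None
    ortholog_upstream: str | None
    ortholog_downstream: str | None
    syntenic: bool
    reason: str
    foreign_lnc_ids: tuple[str, ...] = ()


@dataclass
class ConservationReport:
    """Per-species best hits plus multi-species summary counts."""

    hits: dict[str, dict[str, HitRecord]]
    n_queries: int

    @property
    def conserved_in(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for species, per_query in self.hits.items():
            for qid in per_query:
                out.setdefault(qid, set()).add(species)
        return out

    def fraction_conserved(self, species: str | None = None) -> float:
        if self.n_queries == 0:
            return 0.0
        if species is None:
            return len(self.conserved_in) / self.n_queries
        return len(self.hits.get(species, {})) / self.n_queries


def sequence_conservation(lnc_seqs: dict[str, str],
                          foreign_catalogues: dict[str, dict[str, str]],
                          params: SearchParams | None = None,
                          ) -> ConservationReport:
    """Homology search of each lncRNA against each species' catalogue;
    the best significant hit per lncRNA per species is retained."""
    params = params or SearchParams()
    hits: dict[str, dict[str, HitRecord]] = {}
    for species, catalogue in foreign_catalogues.items():
        if not catalogue:
            raise ValueError(f"catalogue for {species} is empty")
        if not lnc_seqs:
            hits[species] = {}
            continue
        best: dict[str, HitRecord] = {}
        for h in homology_search(lnc_seqs, catalogue, params):
            if h.query_id not in best or h.evalue < best[h.query_id].evalue:
                best[h.query_id] = h
        hits[species] = best
    return ConservationReport(hits, len(lnc_seqs))


class OrthologMapError(KeyError):
    pass


def _between_interval(a: GenomicInterval,
                      b: GenomicInterval) -> GenomicInterval | None:
    """Open interval strictly between two gene bodies (None if they touch
    or overlap)."""
    if a.end < b.start - 1:
        return GenomicInterval(a.chrom, a.end + 1, b.start - 1)
    if b.end < a.start - 1:
        return GenomicInterval(a.chrom, b.end + 1, a.start - 1)
    return None


def synteny_scan(lincRNAs: list[TranscriptModel],
                 reference: ReferenceIndex,
                 ortholog_map: dict[str, dict[str, str]],
                 foreign_gene_positions: dict[str, dict[str, GenomicInterval]],
                 foreign_lnc_positions: dict[str, dict[str, GenomicInterval]],
                 flank_window: int = 1_000_000,
                 ) -> list[SyntenyCall]:
    """Synteny calls for each lincRNA in each species of ``ortholog_map``.

    ``ortholog_map`` is species -> {chicken_gene: foreign_gene}; foreign
    positions are 1-based inclusive.  Flanking genes are the nearest
    protein-coding genes with no distance cap by default
    (``flank_window`` is the search bound).
    """
    for species, mapping in ortholog_map.items():
        known = foreign_gene_positions.get(species, {})
        for cg, fg in mapping.items():
            if fg not in known:
                raise OrthologMapError(
                    f"ortholog map entry {cg} -> {fg} ({species}): foreign "
                    f"gene has no recorded position")
    calls = []
    for model in lincRNAs:
        report = nearest_protein_coding(model, reference, flank_window)
        x, y = report.left_gene, report.right_gene
        for species in sorted(ortholog_map):
            if x is None or y is None or x == y:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         None, None, False,
                                         REASON_NO_FLANKING))
                continue
            mapping = ortholog_map[species]
            xp, yp = mapping.get(x), mapping.get(y)
            if xp is None or yp is None:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         xp, yp, False, REASON_NO_ORTHOLOGS))
                continue
            giv_x = foreign_gene_positions[species][xp]
            giv_y = foreign_gene_positions[species][yp]
            if giv_x.chrom != giv_y.chrom:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         xp, yp, False, REASON_SPLIT_PAIR))
                continue
            between = _between_interval(giv_x, giv_y)
            if between is None:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         xp, yp, False, REASON_OVERLAPPING))
                continue
            matches = tuple(sorted(
                fid for fid, fiv in foreign_lnc_positions[species].items()
                if between.contains(fiv)))
            if matches:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         xp, yp, True, REASON_SYNTENIC,
                                         matches))
            else:
                calls.append(SyntenyCall(model.transcript_id, species, x, y,
                                         xp, yp, False,
                                         REASON_NO_FOREIGN_LNC))
    return calls


def read_ortholog_map(path) -> dict[str, dict[str, str]]:
    """TSV of (chicken_gene, species, foreign_gene) -> nested map."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: need chicken_gene, "
                                 f"species, foreign_gene")
            out.setdefault(cols[1], {})[cols[0]] = cols[2]
    return out


def write_ortholog_map(mapping: dict[str, dict[str, str]], path) -> None:
    with open(path, "w") as fh:
        for species in sorted(mapping):
            for cg in sorted(mapping[species]):
                fh.write(f"{cg}\t{species}\t{mapping[species][cg]}\n")
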