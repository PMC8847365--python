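import numpy as np
import pytest

from lncquarry.classify import (
    ClassCode,
    ReferenceIndex,
    assign_class_code,
    extract_sequence,
    nearest_protein_coding,
    subtype_lncrna,
)
from lncquarry.models import GenomicInterval, TranscriptModel


def tx(tid, chrom, exon_coords, strand="+", gene=None, biotype="unknown"):
    return TranscriptModel(tid, gene or f"gene_{tid}",
                           [GenomicInterval(chrom, s, e, strand)
                            for s, e in exon_coords], biotype)


@pytest.fixture()
def toy_reference():
    return ReferenceIndex([
        # coding gene with two exons 1000-1200 / 2000-2300 (intron 1201-1999)
        tx("ref1.t1", "chr1", [(1000, 1200), (2000, 2300)], "+",
           gene="REF1", biotype="protein_coding"),
        # second coding gene far to the right
        tx("ref2.t1", "chr1", [(10_000, 11_000)], "+", gene="REF2",
           biotype="protein_coding"),
    ])


class TestExtractSequence:
    genome = {"chr1": "AACCGGTT"}

    def test_plus_strand_single_exon(self):
        model = tx("q", "chr1", [(3, 4)])
        assert extract_sequence(model, self.genome) == "CC"

    def test_minus_strand_reverse_complement(self):
        model = tx("q", "chr1", [(3, 4)], "-")
        assert extract_sequence(model, self.genome) == "GG"

    def test_splice_join(self):
        model = tx("q", "chr1", [(1, 2), (7, 8)])
        assert extract_sequence(model, self.genome) == "AATT"

    def test_exon_beyond_chromosome_end(self):
        model = tx("q", "chr1", [(5, 20)])
        with pytest.raises(ValueError, match="beyond"):
            extract_sequence(model, self.genome)


class TestClassCode:
    def test_exon_inside_intron_is_intronic(self, toy_reference):
        query = tx("q", "chr1", [(1400, 1700)])
        code = assign_class_code(query, toy_reference)
        assert code.code == "i"
        assert code.matched_reference_id == "ref1.t1"

    def test_far_from_genes_is_intergenic(self, toy_reference):
        assert assign_class_code(tx("q", "chr1", [(5000, 5400)]),
                                 toy_reference).code == "u"

    def test_identical_intron_chain_is_match(self, toy_reference):
        query = tx("q", "chr1", [(990, 1200), (2000, 2350)])
        assert assign_class_code(query, toy_reference).code == "="

    def test_partial_exon_overlap_is_other(self, toy_reference):
        assert assign_class_code(tx("q", "chr1", [(1100, 1500)]),
                                 toy_reference).code == "o"

    def test_absent_chromosome_classified_intergenic(self, toy_reference):
        assert assign_class_code(tx("q", "chrUn", [(1, 500)]),
                                 toy_reference).code == "u"

    def test_monoexon_match_needs_reciprocal_overlap(self, toy_reference):
        # 80% reciprocal overlap with the mono-exon REF2 transcript
        assert assign_class_code(tx("q", "chr1", [(10_050, 11_000)]),
                                 toy_reference).code == "="
        # tiny overlap fails the reciprocal rule -> other
        assert assign_class_code(tx("q", "chr1", [(10_900, 11_050)]),
                                 toy_reference).code == "o"


class TestNearestProteinCoding:
    def test_left_distance_counts_bases_between(self):
        ref = ReferenceIndex([tx("g.t1", "chr1", [(1, 1000)], "+", gene="G",
                                 biotype="protein_coding")])
        near = nearest_protein_coding(tx("q", "chr1", [(1500, 1600)]),
                                      ref, 10_000)
        assert near.left_gene == "G"
        assert near.left_distance == 499
        assert near.right_gene is None

    def test_no_gene_within_window_reported_empty(self):
        ref = ReferenceIndex([tx("g.t1", "chr1", [(1, 100)], "+", gene="G",
                                 biotype="protein_coding")])
        near = nearest_protein_coding(tx("q", "chr1", [(50_000, 50_100)]),
                                      ref, 10_000)
        assert near.left_gene is None and near.right_gene is None

    def test_equidistant_tie_breaks_on_gene_id(self):
        ref = ReferenceIndex([
            tx("b.t1", "chr1", [(1, 1000)], "+", gene="GB",
               biotype="protein_coding"),
            tx("a.t1", "chr1", [(500, 1000)], "+", gene="GA",
               biotype="protein_coding"),
        ])
        near = nearest_protein_coding(tx("q", "chr1", [(1500, 1600)]),
                                      ref, 10_000)
        assert near.left_gene == "GA"

    def test_window_must_be_positive(self, toy_reference):
        with pytest.raises(ValueError):
            nearest_protein_coding(tx("q", "chr1", [(1, 10)]),
                                   toy_reference, 0)


class TestSubtype:
    @pytest.mark.parametrize("code,expected", [("u", "lincRNA"),
                                               ("i", "ilncRNA")])
    def test_candidate_codes_map_to_subtypes(self, code, expected):
        assert subtype_lncrna(ClassCode(code)) == expected

    @pytest.mark.parametrize("code", ["=", "o"])
    def test_non_candidate_codes_rejected(self, code):
        with pytest.raises(ValueError):
            subtype_lncrna(ClassCode(code, "x"))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_class_code(query, reference_models):
    """Independent all-pairs re-derivation of the class-code definition."""
    overlapping = [r for r in reference_models
                   if r.chrom == query.chrom
                   and r.interval.overlaps(query.interval)]
    for ref in sorted(overlapping, key=lambda r: r.transcript_id):
        strands_ok = (query.strand == ref.strand or "." in
                      (query.strand, ref.strand))
        if strands_ok:
            if query.exon_count == 1 and ref.exon_count == 1:
                ov = query.interval.overlap_length(ref.interval)
                if (ov >= 0.8 * query.length and ov >= 0.8 * ref.length):
                    return "="
            elif (query.exon_count == ref.exon_count
                  and query.intron_chain() == ref.intron_chain()):
                return "="
    gene_spans = {}
    for r in reference_models:
        span = gene_spans.get(r.gene_id)
        iv = r.interval
        if span is None:
            gene_spans[r.gene_id] = [iv.chrom, iv.start, iv.end]
        else:
            span[1] = min(span[1], iv.start)
            span[2] = max(span[2], iv.end)
    hits_gene = any(
        c == query.chrom and s <= query.interval.end
        and query.interval.start <= e
        for c, s, e in gene_spans.values())
    if not hits_gene:
        return "u"
    for ref in overlapping:
        introns = ref.introns
        if introns and all(
                any(i.start <= ex.start and ex.end <= i.end for i in introns)
                for ex in query.exons):
            return "i"
    return "o"


def brute_nearest(query, reference_models, window):
    genes = {}
    for r in reference_models:
        if r.biotype != "protein_coding":
            continue
        entry = genes.setdefault(r.gene_id, [r.chrom, r.interval.start,
                                             r.interval.end])
        entry[1] = min(entry[1], r.interval.start)
        entry[2] = max(entry[2], r.interval.end)
    best_left = best_right = None
    q = query.interval
    for gid, (chrom, s, e) in genes.items():
        if chrom != q.chrom:
            continue
        if s <= q.end and q.start <= e:       # overlap counts on both sides
            for side in ("L", "R"):
                cand = (0, gid)
                if side == "L":
                    best_left = cand if best_left is None else min(best_left,
                                                                   cand)
                else:
                    best_right = cand if best_right is None else min(
                        best_right, cand)
        elif e < q.start:
            d = q.start - e - 1
            if d <= window:
                cand = (d, gid)
                best_left = cand if best_left is None else min(best_left,
                                                               cand)
        else:
            d = s - q.end - 1
            if d <= window:
                cand = (d, gid)
                best_right = cand if best_right is None else min(best_right,
                                                                 cand)
    return best_left, best_right


def _random_query(rng, chroms, chrom_len):
    chrom = chroms[rng.integers(0, len(chroms))]
    start = int(rng.integers(1, chrom_len - 20_000))
    strand = "+-"[rng.integers(0, 2)]
    n_exons = int(rng.integers(1, 4))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(50, 2000))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(50, 3000))
    return TranscriptModel("q", "q_gene",
                           [GenomicInterval(chrom, s, e, strand)
                            for s, e in exons])


def test_class_code_agrees_with_brute_force_scan(world, ref_index):
    rng = np.random.default_rng(5)
    chroms = sorted(world.genome)
    min_len = min(len(s) for s in world.genome.values())
    for _ in range(300):
        query = _random_query(rng, chroms, min_len)
        assert assign_class_code(query, ref_index).code == \
            brute_class_code(query, world.reference)


def test_nearest_gene_agrees_with_brute_force_scan(world, ref_index):
    rng = np.random.default_rng(6)
    chroms = sorted(world.genome)
    min_len = min(len(s) for s in world.genome.values())
    for _ in range(300):
        query = _random_query(rng, chroms, min_len)
        near = nearest_protein_coding(query, ref_index, 50_000)
        bl, br = brute_nearest(query, world.reference, 50_000)
        got_l = (near.left_distance, near.left_gene) if near.left_gene \
            else None
        got_r = (near.right_distance, near.right_gene) if near.right_gene \
            else None
        assert got_l == bl
        assert got_r == br


def test_nearest_gene_is_symmetric_under_coordinate_mirroring():
    chrom_len = 100_000
    genes = [("GA", 5_000, 9_000), ("GB", 30_000, 33_000),
             ("GC", 70_000, 71_000)]
    query_span = (40_000, 41_000)

    def build(flip):
        def mi(s, e):
            return (chrom_len - e + 1, chrom_len - s + 1) if flip else (s, e)
        ref = ReferenceIndex([
            tx(f"{g}.t1", "chr1", [mi(s, e)], "+", gene=g,
               biotype="protein_coding") for g, s, e in genes])
        q = tx("q", "chr1", [mi(*query_span)])
        return nearest_protein_coding(q, ref, 50_000)

    fwd = build(False)
    rev = build(True)
    assert (fwd.left_gene, fwd.left_distance) == (rev.right_gene,
                                                  rev.right_distance)
    assert (fwd.right_gene, fwd.right_distance) == (rev.left_gene,
                                                    rev.left_distance)


def test_each_transcript_gets_exactly_one_code(world, ref_index):
    codes = [assign_class_code(m, ref_index).code for m in world.assembled]
    assert set(codes) <= {"=", "u", "i", "o"}
    assert len(codes) == len(world.assembled)
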