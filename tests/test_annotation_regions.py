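import numpy as np
import pytest

from ssrmine.annotation_regions import (
    GFFParseError,
    assign_loci,
    complement_intervals,
    derive_compartments,
    intersect,
    merge,
    overlaps,
    parse_gff,
    subtract,
    total_bp,
)
from ssrmine.ssr_scanner import SSRLocus

from _oracles import (
    bitmap_complement,
    bitmap_intersect,
    bitmap_overlaps,
    bitmap_subtract,
)


def _locus(seq_id, start, end):
    return SSRLocus(seq_id, start, end, 1, "A", "A", 0)


def _random_intervals(rng, length, n):
    out = []
    for _ in range(int(n)):
        s = int(rng.integers(0, length))
        e = int(rng.integers(s, min(length, s + int(rng.integers(1, 40))) + 1))
        out.append((s, e))
    return merge(out)


# ---------------------------------------------------------------------------
# interval arithmetic


def test_subtract_split_and_annihilation():
    assert subtract([(0, 100)], [(40, 60)]) == [(0, 40), (60, 100)]
    assert subtract([(0, 10)], [(0, 10)]) == []
    assert subtract([], [(0, 10)]) == []
    assert subtract([(0, 10)], []) == [(0, 10)]


def test_merge_sorts_and_coalesces():
    assert merge([(5, 9), (0, 3), (3, 6), (20, 20)]) == [(0, 9)]


def test_interval_ops_match_bitmap_oracle(rng):
    L = 500
    for _ in range(50):
        a = _random_intervals(rng, L, rng.integers(0, 12))
        b = _random_intervals(rng, L, rng.integers(0, 12))
        assert subtract(a, b) == bitmap_subtract(a, b, L)
        assert intersect(a, b) == bitmap_intersect(a, b, L)
        assert complement_intervals(a, L) == bitmap_complement(a, L)


def test_overlaps_matches_bitmap_oracle(rng):
    L = 300
    for _ in range(30):
        ivs = _random_intervals(rng, L, rng.integers(0, 8))
        for _ in range(20):
            s = int(rng.integers(0, L))
            e = int(rng.integers(s, L + 1))
            assert overlaps(ivs, s, e) == bitmap_overlaps(ivs, s, e, L)


# ---------------------------------------------------------------------------
# GFF parsing


def test_parse_gff_coordinate_convention(tmp_path):
    gff = tmp_path / "a.gff3"
    gff.write_text("chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
    assert parse_gff(gff) == {("chr1", "gene"): [(100, 200)]}


def test_parse_gff_merges_isoform_exons_and_matches_case(tmp_path):
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "chr1\t.\tExon\t1\t100\t.\t+\t.\tID=e1\n"
        "chr1\t.\texon\t50\t150\t.\t+\t.\tID=e2\n"
        "chr1\t.\tCDS\t10\t90\t.\t+\t0\tID=c1\n"
        "chr1\t.\tmRNA\t1\t150\t.\t+\t.\tID=m1\n"  # ignored type
    )
    feats = parse_gff(gff)
    assert feats[("chr1", "exon")] == [(0, 150)]
    assert feats[("chr1", "CDS")] == [(9, 90)]
    assert ("chr1", "mRNA") not in feats


def test_parse_gff_empty_and_comments(tmp_path):
    gff = tmp_path / "a.gff3"
    gff.write_text("##gff-version 3\n\n")
    assert parse_gff(gff) == {}


def test_parse_gff_rejects_reversed_row_with_warning(tmp_path, caplog):
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "chr1\t.\tgene\t200\t100\t.\t+\t.\tID=bad\n"
        "chr1\t.\tgene\t300\t400\t.\t+\t.\tID=ok\n"
    )
    with caplog.at_level("WARNING"):
        feats = parse_gff(gff)
    assert feats == {("chr1", "gene"): [(299, 400)]}
    assert any("end < start" in rec.message for rec in caplog.records)


@pytest.mark.parametrize(
    "line", ["chr1\tgene\t1\t10\n", "chr1\t.\tgene\tone\tten\t.\t+\t.\tID=x\n"]
)
def test_parse_gff_raises_with_line_number(tmp_path, line):
    gff = tmp_path / "a.gff3"
    gff.write_text("##gff-version 3\n" + line)
    with pytest.raises(GFFParseError, match="line 2"):
        parse_gff(gff)


# ---------------------------------------------------------------------------
# compartments


def _textbook_cmap(L=1000, convention="complement"):
    feats = {
        ("chr1", "gene"): [(100, 500)],
        ("chr1", "exon"): [(100, 200), (300, 500)],
        ("chr1", "CDS"): [(130, 200), (300, 470)],
    }
    return derive_compartments(feats, {"chr1": L}, convention)


def test_textbook_gene_model():
    cmap = _textbook_cmap()
    assert cmap.intron["chr1"] == [(200, 300)]
    assert cmap.intergenic["chr1"] == [(0, 100), (500, 1000)]
    assert cmap.exon["chr1"] == [(100, 200), (300, 500)]


def test_between_convention_excludes_sequence_ends():
    feats = {("chr1", "gene"): [(100, 200), (400, 500)]}
    cmap = derive_compartments(feats, {"chr1": 1000}, "between")
    assert cmap.intergenic["chr1"] == [(200, 400)]


def test_unannotated_sequence_is_wholly_intergenic():
    cmap = derive_compartments({}, {"chr1": 777})
    assert cmap.intergenic["chr1"] == [(0, 777)]
    assert cmap.gene["chr1"] == [] and cmap.intron["chr1"] == []


def test_feature_clipped_to_sequence_length(caplog):
    with caplog.at_level("WARNING"):
        cmap = derive_compartments({("c", "gene"): [(10, 50)]}, {"c": 30})
    assert cmap.gene["c"] == [(10, 30)]
    assert any("clipped" in rec.message for rec in caplog.records)


def test_unknown_intergenic_convention_rejected():
    with pytest.raises(ValueError):
        derive_compartments({}, {"c": 10}, "outside")


def test_partition_and_conservation_on_random_annotations(rng):
    L = 2000
    for _ in range(30):
        gene = _random_intervals(rng, L, rng.integers(0, 6))
        exon = merge(
            [iv for g in gene for iv in _random_intervals(rng, L, 2) if iv[0] >= g[0]]
        )
        feats = {("c", "gene"): gene, ("c", "exon"): exon}
        cmap = derive_compartments(feats, {"c": L})
        # gene and intergenic partition [0, L)
        assert total_bp(cmap.gene["c"]) + total_bp(cmap.intergenic["c"]) == L
        assert intersect(cmap.gene["c"], cmap.intergenic["c"]) == []
        # intron + exon-within-gene = gene
        assert total_bp(cmap.intron["c"]) + total_bp(intersect(exon, gene)) == total_bp(gene)
        assert intersect(cmap.intron["c"], cmap.exon["c"]) == []
        assert subtract(cmap.intron["c"], gene) == []  # intron within genes


# ---------------------------------------------------------------------------
# assignment


def test_assignment_textbook_examples():
    cmap = _textbook_cmap()
    by_locus = {
        (a.locus.start, a.locus.end): set(a.compartments)
        for a in assign_loci(
            [_locus("chr1", 150, 170), _locus("chr1", 195, 205), _locus("chr1", 50, 60)],
            cmap,
        )
    }
    assert by_locus[(150, 170)] == {"exon", "CDS"}
    assert by_locus[(195, 205)] == {"exon", "intron", "CDS"}  # >=1 bp each side
    assert by_locus[(50, 60)] == {"intergenic"}


def test_assignment_on_unannotated_sequence_defaults_to_intergenic(caplog):
    cmap = _textbook_cmap()
    with caplog.at_level("INFO"):
        (a,) = assign_loci([_locus("scaffold9", 0, 20)], cmap)
    assert a.compartments == {"intergenic"}


def test_assignment_matches_bitmap_oracle(rng):
    L = 1500
    for _ in range(15):
        gene = _random_intervals(rng, L, 4)
        exon = intersect(_random_intervals(rng, L, 6), gene)
        cds = intersect(_random_intervals(rng, L, 4), exon)
        cmap = derive_compartments(
            {("c", "gene"): gene, ("c", "exon"): exon, ("c", "CDS"): cds}, {"c": L}
        )
        comp_intervals = {
            "CDS": cmap.cds["c"], "exon": cmap.exon["c"],
            "intron": cmap.intron["c"], "intergenic": cmap.intergenic["c"],
        }
        loci = [
            _locus("c", s, min(L, s + int(rng.integers(1, 30))))
            for s in rng.integers(0, L - 1, size=25)
        ]
        for a in assign_loci(loci, cmap):
            expected = {
                name
                for name, ivs in comp_intervals.items()
                if bitmap_overlaps(ivs, a.locus.start, a.locus.end, L)
            }
            assert set(a.compartments) == expected


def test_assignment_is_monotone_under_enlargement(rng):
    cmap = _textbook_cmap()
    for _ in range(50):
        s = int(rng.integers(0, 990))
        e = int(rng.integers(s + 1, 1000))
        (small,) = assign_loci([_locus("chr1", s, e)], cmap)
        (big,) = assign_loci([_locus("chr1", max(0, s - 10), min(1000, e + 10))], cmap)
        assert small.compartments <= big.compartments
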