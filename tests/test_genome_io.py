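"""Genome I/O: coordinates, strands, gaps, gene-order typing, round trips."""

import textwrap

import pytest

from mitotrna.genome_io import (
    GENE_ORDER_TEMPLATES,
    AnnotatedGenome,
    ClassificationError,
    GapRegion,
    GeneFeature,
    Genome,
    classify_gene_order,
    extract_gaps,
    read_feature_table,
    read_genbank,
    write_feature_table,
    write_genbank,
)
from mitotrna._vocab import normalize_gene_name, revcomp


def _toy_record(path, body, length=60, seq=None):
    seq = seq or ("ACGT" * (length // 4 + 1))[:length]
    lines = [f"LOCUS       toy       {length} bp    DNA     circular     01-JAN-2000"]
    lines.append("FEATURES             Location/Qualifiers")
    lines.extend(body)
    lines.append("ORIGIN")
    for i in range(0, length, 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
    return seq


def test_coordinate_convention_1based_to_half_open(tmp_path):
    p = tmp_path / "toy.gb"
    _toy_record(p, ['     gene            1..30', '                     /gene="cox1"'])
    ag = read_genbank(p)
    f = ag.get("cox1")
    assert (f.start, f.end, f.strand) == (0, 30, "J")


def test_complement_feature_maps_to_n_strand_and_revcomp(tmp_path):
    p = tmp_path / "toy.gb"
    seq = _toy_record(
        p,
        [
            '     gene            1..40', '                     /gene="cox1"',
            '     gene            complement(45..56)', '                     /gene="trnK"',
        ],
    )
    ag = read_genbank(p)
    f = ag.get("trnK")
    assert f.strand == "N"
    assert f.sequence(ag.genome) == revcomp(seq[44:56])


@pytest.mark.parametrize(
    "raw,anticodon,expected",
    [
        ("tRNA-Ser", "TGA", "trnS2"),
        ("tRNA-Ser(AGN)", None, "trnS1"),
        ("tRNA-Leu", "TAA", "trnL2"),
        ("tRNA-Leu(CUN)", None, "trnL1"),
        ("ND4L", None, "nad4L"),
        ("cytochrome c oxidase subunit 1", None, "cox1"),
        ("16S ribosomal RNA", None, "rrnL"),
        ("l-rRNA", None, "rrnL"),
        ("CYTB", None, "cob"),
        ("mystery ORF", None, None),
    ],
)
def test_gene_name_normalization(raw, anticodon, expected):
    assert normalize_gene_name(raw, anticodon=anticodon) == expected


def test_two_gene_circle_yields_only_in_window_gap():
    g = Genome(id="c", sequence="A" * 200)
    ag = AnnotatedGenome(
        genome=g,
        features=[
            GeneFeature("cox1", "PCG", "J", 0, 100),
            GeneFeature("cob", "PCG", "J", 150, 190),
        ],
    )
    gaps = extract_gaps(ag, 46, 215)
    assert len(gaps) == 1
    (gap,) = gaps
    assert (gap.length, gap.left_flank, gap.right_flank) == (50, "cox1", "cob")
    assert gap.start == 100


def test_fully_annotated_genome_has_no_gaps():
    g = Genome(id="c", sequence="A" * 100)
    ag = AnnotatedGenome(genome=g, features=[GeneFeature("cox1", "PCG", "J", 0, 100)])
    assert extract_gaps(ag, 1, 100) == []


def test_origin_wrapping_gap_is_found():
    g = Genome(id="c", sequence="A" * 200)
    ag = AnnotatedGenome(
        genome=g,
        features=[
            GeneFeature("cox1", "PCG", "J", 30, 100),
            GeneFeature("cob", "PCG", "J", 120, 180),
        ],
    )
    gaps = extract_gaps(ag, 46, 215)
    wrap = [x for x in gaps if x.end > 200]
    assert len(wrap) == 1
    assert wrap[0].start == 180 and wrap[0].end == 230 and wrap[0].length == 50


def test_gap_feature_partition_covers_circle(syn_genome):
    """Features and (unwindowed) gaps partition the circle exactly once."""
    ag = syn_genome.truth
    L = ag.genome.length
    gaps = extract_gaps(ag, 1, L, treat_cr_as_gap=False)
    total = sum(f.length for f in ag.features) + sum(x.length for x in gaps)
    assert total == L


def test_gap_parameter_validation(syn_genome):
    with pytest.raises(ValueError):
        extract_gaps(syn_genome.truth, 100, 50)


def _template_annotation(type_name, rotate=0, width=10):
    entries = [e for e in GENE_ORDER_TEMPLATES[type_name] if e[0] != "CR"]
    entries = entries[rotate:] + entries[:rotate]
    L = width * len(entries)
    feats = [
        GeneFeature(
            name,
            "PCG" if name[0] not in ("t", "r") else ("rRNA" if name.startswith("rrn") else "tRNA"),
            strand,
            i * width,
            (i + 1) * width,
        )
        for i, (name, strand) in enumerate(entries)
    ]
    return AnnotatedGenome(genome=Genome(id=type_name, sequence="A" * L), features=feats)


@pytest.mark.parametrize("type_name", ["I", "II", "III", "IV", "V"])
def test_each_template_classifies_to_its_own_type(type_name):
    assert classify_gene_order(_template_annotation(type_name)) == type_name


@pytest.mark.parametrize("rotate", [1, 7, 20, 33])
def test_classification_is_rotation_invariant(rotate):
    for type_name in GENE_ORDER_TEMPLATES:
        assert classify_gene_order(_template_annotation(type_name, rotate=rotate)) == type_name


def test_shuffled_order_is_novel():
    ag = _template_annotation("I")
    feats = list(ag.features)
    # swap two distant PCGs to break every template
    i = next(k for k, f in enumerate(feats) if f.name == "cox2")
    j = next(k for k, f in enumerate(feats) if f.name == "nad5")
    fi, fj = feats[i], feats[j]
    feats[i] = GeneFeature(fj.name, fj.kind, fi.strand, fi.start, fi.end)
    feats[j] = GeneFeature(fi.name, fi.kind, fj.strand, fj.start, fj.end)
    assert classify_gene_order(AnnotatedGenome(genome=ag.genome, features=feats)) == "novel"


def test_too_few_genes_raises():
    ag = _template_annotation("I")
    few = AnnotatedGenome(genome=ag.genome, features=list(ag.features)[:20])
    with pytest.raises(ClassificationError):
        classify_gene_order(few)


def test_classification_skips_missing_genes_in_both():
    """A full Type-I annotation does not collapse onto the reduced Type IV."""
    assert classify_gene_order(_template_annotation("I")) == "I"
    assert classify_gene_order(_template_annotation("IV")) == "IV"


def test_genbank_and_feature_table_round_trips(tmp_path, syn_genome):
    """GenBank -> model -> feature table -> model preserves all coordinates."""
    truth = syn_genome.truth
    gb = tmp_path / "g.gb"
    write_genbank(truth, gb)
    back = read_genbank(gb)
    key = lambda ag: {(f.name, f.strand, f.start, f.end) for f in ag.features}
    assert key(back) == key(truth)
    tsv = tmp_path / "g.tsv"
    write_feature_table(back, tsv)
    again = read_feature_table(tsv, back.genome)
    assert key(again) == key(truth)
    assert (tmp_path / "g.gff3").exists()


def test_feature_table_row_count(tmp_path):
    g = Genome(id="c", sequence="A" * 100)
    ag = AnnotatedGenome(
        genome=g,
        features=[
            GeneFeature("cox1", "PCG", "J", 0, 60),
            GeneFeature("trnK", "tRNA", "J", 70, 90, anticodon="CTT"),
        ],
    )
    p = tmp_path / "t.tsv"
    write_feature_table(ag, p)
    rows = [l for l in p.read_text().splitlines() if l and not l.startswith("#")]
    assert len(rows) == 1 + 2  # header + two features


def test_ambiguity_codes_rejected():
    with pytest.raises(ValueError):
        Genome(id="bad", sequence="ACGTN")
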