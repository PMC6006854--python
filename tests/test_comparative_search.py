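"""Missing-identity logic, anticodon tables, gap scanning, scoring, recovery."""

import pytest

from mitotrna._vocab import STANDARD_ANTICODONS, TRNA_IDENTITIES, revcomp
from mitotrna.comparative_search import (
    AnticodonMode,
    AnticodonTable,
    Candidate,
    PanelEntry,
    RecoverConfig,
    ReferencePanel,
    missing_trnas,
    recover,
    scan_gap,
    score_conservation,
)
from mitotrna.genome_io import AnnotatedGenome, GapRegion, GeneFeature, Genome
from mitotrna.trna_structure import Topology, TrnaStructure


def _drop(ag, names):
    return AnnotatedGenome(
        genome=ag.genome, features=[f for f in ag.features if f.name not in names]
    )


def test_missing_trnas_complete_annotation(syn_genome):
    assert missing_trnas(syn_genome.truth) == set()


@pytest.mark.parametrize(
    "absent",
    [
        {"trnA", "trnY"},               # the scabies-mite pair
        {"trnF", "trnS1", "trnQ"},      # the Tyrophagus triple
    ],
)
def test_missing_trnas_reports_absent_identities(syn_genome, absent):
    assert missing_trnas(_drop(syn_genome.truth, absent)) == absent


def test_anticodon_table_paper_alternatives_exact():
    table = AnticodonTable(AnticodonMode.PAPER_ALTERNATIVES)
    expected = {
        "trnE": "CTC", "trnI": "AAT", "trnC": "ACA",
        "trnQ": "CTG", "trnF": "AAA", "trnS1": "ACT",
    }
    for identity in TRNA_IDENTITIES:
        pairs = table.anticodons(identity)
        assert pairs[0] == (STANDARD_ANTICODONS[identity], False)
        alts = [t for t, is_alt in pairs if is_alt]
        if identity in expected:
            assert alts == [expected[identity]]
        else:
            assert alts == []


def test_anticodon_mode_monotonicity():
    """standard_only <= paper_alternatives <= all_synonymous triplet sets."""
    t_std = AnticodonTable(AnticodonMode.STANDARD_ONLY)
    t_alt = AnticodonTable(AnticodonMode.PAPER_ALTERNATIVES)
    t_all = AnticodonTable(AnticodonMode.ALL_SYNONYMOUS)
    for identity in TRNA_IDENTITIES:
        s = {x for x, _ in t_std.anticodons(identity)}
        a = {x for x, _ in t_alt.anticodons(identity)}
        u = {x for x, _ in t_all.anticodons(identity)}
        assert s <= a <= u


def test_all_synonymous_anticodons_decode_the_right_codons():
    from mitotrna.codon_usage import GeneticCode, identity_of_codon

    code = GeneticCode()
    table = AnticodonTable(AnticodonMode.ALL_SYNONYMOUS)
    for identity in TRNA_IDENTITIES:
        for triplet, _ in table.anticodons(identity):
            assert identity_of_codon(revcomp(triplet), code) == identity


def _gap_genome(gap_seq: str):
    """A toy circular genome whose single in-window gap is ``gap_seq``."""
    left = "C" * 60
    right = "G" * 60
    seq = left + gap_seq + right + "C" * 40
    g = Genome(id="toy", sequence=seq)
    ag = AnnotatedGenome(
        genome=g,
        features=[
            GeneFeature("cox1", "PCG", "J", 0, 60),
            GeneFeature("cob", "PCG", "J", 60 + len(gap_seq), 120 + len(gap_seq)),
            GeneFeature("nad1", "PCG", "J", 120 + len(gap_seq), len(seq)),
        ],
    )
    gap = GapRegion(start=60, end=60 + len(gap_seq), left_flank="cox1", right_flank="cob")
    return g, gap


def test_scan_gap_finds_standard_anchor_on_both_strands():
    gap_seq = "A" * 20 + "GAA" + "A" * 37  # one trnF anchor, J strand
    g, gap = _gap_genome(gap_seq)
    hits = scan_gap(gap, "trnF", AnticodonTable(AnticodonMode.STANDARD_ONLY), g)
    j_hits = [h for h in hits if h[0] == "J"]
    assert [h[1] for h in j_hits] == [20]
    assert all(h[2] == "GAA" for h in j_hits)
    # the reverse complement of the gap contains TTC, not GAA
    assert all(h[0] == "J" for h in hits)


def test_scan_gap_alternative_anticodon_adds_anchors():
    gap_seq = "T" * 20 + "GAA" + "T" * 10 + "AAA" + "T" * 24
    g, gap = _gap_genome(gap_seq)
    std = scan_gap(gap, "trnF", AnticodonTable(AnticodonMode.STANDARD_ONLY), g)
    alt = scan_gap(gap, "trnF", AnticodonTable(AnticodonMode.PAPER_ALTERNATIVES), g)
    assert {h[1] for h in std if h[0] == "J"} == {20}
    assert {h[1] for h in alt if h[0] == "J"} == {20, 33}
    assert any(h[3] for h in alt)  # flagged as alternative


def test_scan_gap_requires_flanking_room():
    gap_seq = "GAA" + "T" * 57  # anchor at offset 0: no 5' flank
    g, gap = _gap_genome(gap_seq)
    hits = scan_gap(gap, "trnF", AnticodonTable(AnticodonMode.STANDARD_ONLY), g)
    assert all(h[1] != 0 for h in hits)


def _block_structure(block: str, stem: int = 5) -> TrnaStructure:
    """A minimal structure exposing only the anticodon arm + loop."""
    loop_s = stem
    return TrnaStructure(
        sequence=block,
        topology=Topology.ARMLESS,
        arms=(
            ("ac5", 0, stem),
            ("acloop", loop_s, loop_s + 7),
            ("ac3", loop_s + 7, loop_s + 7 + stem),
        ),
        mismatches=(("aa", 0), ("ac", 0)),
        anticodon=block[loop_s + 2 : loop_s + 5],
        ac_offset=loop_s + 2,
        structure_penalty=4.0,
    )


def test_conservation_identical_homolog_scores_one():
    block = "GCGCG" + "TTGAATT" + "CGCGC"
    s = _block_structure(block)
    panel = ReferencePanel(entries={"trnF": [PanelEntry("sp", block, 5, 12)]})
    assert score_conservation(s, panel, "trnF") == 1.0


def test_conservation_loop_only_match_is_seven_seventeenths():
    loop = "TTGAATT"
    cand = _block_structure("AAAAA" + loop + "AAAAA")
    homolog = "GGGGG" + loop + "CCCCC"
    panel = ReferencePanel(entries={"trnF": [PanelEntry("sp", homolog, 5, 12)]})
    assert score_conservation(cand, panel, "trnF") == pytest.approx(7 / 17)


def test_conservation_against_masked_homolog_is_zero():
    cand = _block_structure("GCGCG" + "TTGAATT" + "CGCGC")
    panel = ReferencePanel(entries={"trnF": [PanelEntry("sp", "N" * 17, 5, 12)]})
    assert score_conservation(cand, panel, "trnF") == 0.0


def test_conservation_empty_panel_is_an_error():
    cand = _block_structure("GCGCG" + "TTGAATT" + "CGCGC")
    with pytest.raises(ValueError):
        score_conservation(cand, ReferencePanel(), "trnF")


def test_recover_finds_all_stripped_identities(syn_genome, syn_panel, synthetic_recover_cfg):
    result = recover(syn_genome.stripped, syn_panel, synthetic_recover_cfg)
    stripped = set(syn_genome.spec.strip)
    assert set(result.best) == stripped
    for identity in stripped:
        cand = result.best[identity]
        assert cand is not None, f"{identity} not recovered"
        truth = syn_genome.planted[identity]
        assert cand.strand == truth.strand
        ov = min(cand.end, truth.end) - max(cand.start, truth.start)
        assert ov / (truth.end - truth.start) >= 0.5


def test_reported_candidates_anchor_and_caps(syn_genome, syn_panel, synthetic_recover_cfg):
    """Every report carries an allowed anticodon at its stated position and
    never exceeds a mismatch cap."""
    result = recover(syn_genome.stripped, syn_panel, synthetic_recover_cfg)
    table = AnticodonTable(synthetic_recover_cfg.anticodon_mode)
    caps = synthetic_recover_cfg.constraints.caps
    g = syn_genome.genome
    for identity, cand in result.recovered().items():
        allowed = {t for t, _ in table.anticodons(identity)}
        assert cand.anticodon in allowed
        gene_seq = g.fetch(cand.start, cand.end)
        if cand.strand == "N":
            gene_seq = revcomp(gene_seq)
        off = cand.structure.ac_offset
        assert gene_seq[off : off + 3] == cand.anticodon
        for stem, count in cand.structure.mismatches:
            assert count <= caps[stem]


def test_recovered_genes_do_not_overlap(syn_genome, syn_panel, synthetic_recover_cfg):
    spans = [
        (c.start, c.end)
        for c in recover(syn_genome.stripped, syn_panel, synthetic_recover_cfg).recovered().values()
    ]
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


def test_recovery_is_deterministic(syn_genome, syn_panel, synthetic_recover_cfg):
    r1 = recover(syn_genome.stripped, syn_panel, synthetic_recover_cfg)
    r2 = recover(syn_genome.stripped, syn_panel, synthetic_recover_cfg)
    assert r1.to_json() == r2.to_json()
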