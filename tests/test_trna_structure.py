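"""Folding: pairing predicate, geometry enumeration, penalties, invariants."""

import pytest
from hypothesis import given, strategies as st

from brute_oracle import descriptor_set, enumerate_structures
from mitotrna.synthetic_data import TrnaSpec, make_trna
from mitotrna.trna_structure import (
    DEFAULT_PENALTY_WEIGHTS,
    FoldConstraints,
    Topology,
    TrnaStructure,
    can_pair,
    fold_around_anticodon,
    structure_penalty,
)


@pytest.mark.parametrize(
    "b1,b2,wobble,expected",
    [
        ("A", "T", True, True),
        ("A", "U", True, True),
        ("C", "G", False, True),
        ("G", "T", True, True),   # G-U wobble bond
        ("G", "T", False, False),
        ("A", "C", True, False),
        ("A", "A", True, False),
    ],
)
def test_can_pair(b1, b2, wobble, expected):
    assert can_pair(b1, b2, allow_wobble=wobble) is expected


def test_can_pair_rejects_invalid_base():
    with pytest.raises(ValueError):
        can_pair("N", "A")


def _perfect(topology, total, identity="trnF", anticodon="GAA", seed=5, **mm):
    mismatches = tuple(mm.items())
    spec = TrnaSpec(identity, topology, anticodon, mismatches=mismatches, total_len=total)
    return make_trna(spec, seed=seed)


def test_perfect_t_armless_folds_with_zero_mismatches():
    seq, truth = _perfect(Topology.T_ARMLESS, 54)
    structures = fold_around_anticodon(seq, truth.ac_offset)
    assert structures, "a cleanly constructed gene must fold"
    hits = [
        s
        for s in structures
        if s.topology is Topology.T_ARMLESS
        and all(c == 0 for _, c in s.mismatches)
        and s.segment_lengths() == truth.segment_lengths()
    ]
    assert hits, "the planted geometry must be among the returned structures"


def test_broken_aa_stem_removes_planted_geometry():
    seq, truth = _perfect(Topology.T_ARMLESS, 54)
    # five point substitutions in the AA-stem 5' half break > 4 pairs
    s5_start, s5_end = truth.arm_map["aa5"]
    broken = list(seq)
    flip = {"A": "C", "T": "C", "G": "A", "C": "A"}
    for i in range(s5_start, s5_start + 5):
        broken[i] = flip[seq[(s5_end - 1) - (i - s5_start)]]  # clash with partner
    broken = "".join(broken)
    structures = fold_around_anticodon(broken, truth.ac_offset)
    assert not any(
        s.segment_lengths() == truth.segment_lengths() and s.topology is truth.topology
        for s in structures
    ), "no structure may keep that AA-stem placement within the 4-mismatch cap"


def test_short_sequence_below_length_window_returns_nothing():
    assert fold_around_anticodon("ACGTACGTACGTACGTACGT", 10) == []


def test_anticodon_outside_sequence_is_an_error():
    with pytest.raises(ValueError):
        fold_around_anticodon("ACGT" * 15, 59)


@pytest.mark.parametrize(
    "topology,mm,expected",
    [
        (Topology.CLOVERLEAF, {}, 0.0),
        (Topology.T_ARMLESS, {"aa": 1}, 3.0),  # 1 mismatch + one missing arm
        (Topology.ARMLESS, {}, 4.0),           # two missing arms, perfect stems
    ],
)
def test_structure_penalty_formula(topology, mm, expected):
    total = {Topology.CLOVERLEAF: 56, Topology.T_ARMLESS: 54, Topology.ARMLESS: 50}[topology]
    _seq, truth = _perfect(topology, total, **mm)
    assert structure_penalty(truth) == expected
    assert truth.structure_penalty == expected


def _oracle_cases():
    cases = []
    for i, (topo, total) in enumerate(
        [
            (Topology.CLOVERLEAF, 52),
            (Topology.CLOVERLEAF, 63),
            (Topology.D_ARMLESS, 48),
            (Topology.T_ARMLESS, 47),
            (Topology.T_ARMLESS, 55),
            (Topology.ARMLESS, 47),
            (Topology.ARMLESS, 52),
        ]
    ):
        seq, truth = _perfect(topo, total, seed=100 + i)
        cases.append((seq, truth.ac_offset))
        # a mutated variant stresses the cap filters
        mutated = seq[: total // 2] + ("A" if seq[total // 2] != "A" else "G") + seq[total // 2 + 1 :]
        cases.append((mutated, truth.ac_offset))
    return cases


@pytest.mark.parametrize("seq,offset", _oracle_cases())
def test_fold_equals_brute_force_enumeration(seq, offset):
    """The optimized enumerator and an independent exhaustive one agree."""
    constraints = FoldConstraints()
    got = descriptor_set(fold_around_anticodon(seq, offset, constraints))
    expected = enumerate_structures(seq, offset, constraints)
    assert got == expected


def test_cap_monotonicity():
    """Tightening a mismatch cap never adds structures; widening never removes."""
    seq, truth = _perfect(Topology.D_ARMLESS, 55, seed=7, aa=2, ac=1)
    loose = FoldConstraints()
    tight = FoldConstraints(max_mismatch=(("aa", 2), ("ac", 1), ("d", 0), ("t", 0)))
    wide = FoldConstraints(max_mismatch=(("aa", 5), ("ac", 3), ("d", 2), ("t", 2)))
    got_loose = descriptor_set(fold_around_anticodon(seq, truth.ac_offset, loose))
    got_tight = descriptor_set(fold_around_anticodon(seq, truth.ac_offset, tight))
    got_wide = descriptor_set(fold_around_anticodon(seq, truth.ac_offset, wide))
    assert got_tight <= got_loose <= got_wide


def test_self_consistency_of_reported_mismatches():
    """Recounting mismatches from (sequence, intervals) reproduces the stored counts."""
    seq, truth = _perfect(Topology.CLOVERLEAF, 58, seed=9, aa=3, ac=2, d=1, t=1)
    for s in fold_around_anticodon(seq, truth.ac_offset):
        m = s.arm_map
        for stem, five, three in (("aa", "aa5", "aa3"), ("d", "d5", "d3"),
                                  ("ac", "ac5", "ac3"), ("t", "t5", "t3")):
            if five not in m:
                continue
            (s5, e5), (s3, e3) = m[five], m[three]
            count = sum(
                0 if can_pair(s.sequence[s5 + i], s.sequence[e3 - 1 - i]) else 1
                for i in range(e5 - s5)
            )
            assert count == s.mismatch_counts[stem]
        # intervals tile the sequence exactly
        pos = 0
        for _name, a, b in s.arms:
            assert a == pos
            pos = b
        assert pos == s.length


@given(st.integers(0, 2**31 - 1))
def test_sorted_by_penalty(seed):
    seq, truth = make_trna(
        TrnaSpec("trnF", Topology.D_ARMLESS, "GAA", mismatches=(("aa", 2),), total_len=50),
        seed=seed % 1000,
    )
    structures = fold_around_anticodon(seq, truth.ac_offset)
    penalties = [s.structure_penalty for s in structures]
    assert penalties == sorted(penalties)
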