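"""Constrained folding of candidate sequences into truncated tRNA topologies.

A candidate gene is folded *around a fixed anticodon*: the anticodon triplet
occupies positions 3-5 of a 7-nt anticodon loop, and the surrounding sequence
is tiled into stems, loops and connectors according to one of four topologies:

* ``CLOVERLEAF``  aa5 . D-arm . AC-arm . variable loop . T-arm . aa3
* ``D_ARMLESS``   aa5 . connector . AC-arm . variable loop . T-arm . aa3
* ``T_ARMLESS``   aa5 . D-arm . AC-arm . connector . aa3
* ``ARMLESS``     aa5 . connector . AC-arm . connector . aa3

The aminoacyl-acceptor (AA) stem is fixed at 7 bp and the anticodon loop at
7 nt; all other segment lengths range over explicit windows.  Stem halves are
paired position-wise (Watson-Crick, optionally G-U wobble) and a geometry is
kept only when every per-stem mismatch count is within its cap.  Highly
degenerate mitochondrial tRNAs of sarcoptiform mites (47-63 nt, up to 4
AA-stem and 2 AC-stem mismatches, missing D- and/or T-arms) are exactly the
regime these constraints describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

__all__ = [
    "Topology",
    "FoldConstraints",
    "TrnaStructure",
    "can_pair",
    "fold_around_anticodon",
    "fold_at_anchor",
    "structure_penalty",
    "DEFAULT_PENALTY_WEIGHTS",
]


class Topology(str, Enum):
    CLOVERLEAF = "CLOVERLEAF"
    D_ARMLESS = "D_ARMLESS"
    T_ARMLESS = "T_ARMLESS"
    ARMLESS = "ARMLESS"

    @property
    def missing_arms(self) -> int:
        return {"CLOVERLEAF": 0, "D_ARMLESS": 1, "T_ARMLESS": 1, "ARMLESS": 2}[self.value]


_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
_BASES = frozenset("ACGT")


def can_pair(b1: str, b2: str, allow_wobble: bool = True) -> bool:
    """Watson-Crick pairing predicate, with optional G-U wobble.

    Bases are given in the DNA alphabet (T stands for U).
    """
    b1, b2 = b1.upper().replace("U", "T"), b2.upper().replace("U", "T")
    if b1 not in _BASES or b2 not in _BASES:
        raise ValueError(f"invalid base pair ({b1!r}, {b2!r})")
    pair = (b1, b2)
    return pair in _WC or (allow_wobble and pair in _WOBBLE)


@dataclass(frozen=True)
class FoldConstraints:
    """Geometric windows and per-stem mismatch caps for the fold search.

    Lengths are in nucleotides (loops, connectors) or base pairs (stems);
    ranges are inclusive.  ``armless_connector_len`` widens the connector
    window for the doubly truncated topology, which otherwise could not reach
    the 47-63 nt gene lengths observed for armless tRNAs.
    """

    aa_stem_len: int = 7
    ac_stem_len: tuple[int, int] = (4, 5)
    d_stem_len: tuple[int, int] = (3, 4)
    t_stem_len: tuple[int, int] = (3, 5)
    d_loop_len: tuple[int, int] = (3, 10)
    t_loop_len: tuple[int, int] = (3, 10)
    ac_loop_len: int = 7
    connector_len: tuple[int, int] = (1, 6)
    armless_connector_len: tuple[int, int] = (1, 12)
    variable_loop_len: tuple[int, int] = (1, 6)
    total_len: tuple[int, int] = (45, 75)
    max_mismatch: tuple[tuple[str, int], ...] = (
        ("aa", 4), ("ac", 2), ("d", 1), ("t", 1),
    )
    allow_wobble: bool = True

    @property
    def caps(self) -> dict[str, int]:
        return dict(self.max_mismatch)

    def __post_init__(self):
        for lo, hi in (
            self.ac_stem_len, self.d_stem_len, self.t_stem_len, self.d_loop_len,
            self.t_loop_len, self.connector_len, self.armless_connector_len,
            self.variable_loop_len, self.total_len,
        ):
            if lo > hi or lo < 0:
                raise ValueError("empty or negative constraint range")
        if any(v < 0 for _, v in self.max_mismatch):
            raise ValueError("mismatch caps must be non-negative")


DEFAULT_PENALTY_WEIGHTS: dict[str, float] = {
    "aa": 1.0, "ac": 1.0, "d": 1.0, "t": 1.0, "missing_arm": 2.0,
}


@dataclass(frozen=True)
class TrnaStructure:
    """One folded geometry: segment tiling, per-stem mismatches, penalty."""

    sequence: str
    topology: Topology
    arms: tuple[tuple[str, int, int], ...]  # (segment, start, end) tiling the sequence
    mismatches: tuple[tuple[str, int], ...]  # per-stem counts
    anticodon: str
    ac_offset: int  # anticodon start within the sequence
    structure_penalty: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mismatch_counts(self) -> dict[str, int]:
        return dict(self.mismatches)

    @property
    def arm_map(self) -> dict[str, tuple[int, int]]:
        return {name: (s, e) for name, s, e in self.arms}

    def segment_lengths(self) -> tuple[tuple[str, int], ...]:
        return tuple((name, e - s) for name, s, e in self.arms)

    def dot_bracket(self) -> str:
        """Dot-bracket string pairing each stem's halves."""
        out = ["." for _ in self.sequence]
        m = self.arm_map
        for five, three in (("aa5", "aa3"), ("d5", "d3"), ("ac5", "ac3"), ("t5", "t3")):
            if five in m and three in m:
                s5, e5 = m[five]
                s3, e3 = m[three]
                for i in range(e5 - s5):
                    out[s5 + i] = "("
                    out[e3 - 1 - i] = ")"
        return "".join(out)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "topology": self.topology.value,
            "arms": {name: [s, e] for name, s, e in self.arms},
            "mismatches": dict(self.mismatches),
            "anticodon": self.anticodon,
            "ac_offset": self.ac_offset,
            "structure_penalty": self.structure_penalty,
            "dot_bracket": self.dot_bracket(),
        }


# ---------------------------------------------------------------------------
# Geometry enumeration
# ---------------------------------------------------------------------------

#: a geometry is the ordered list of (segment name, length); stems appear as
#: paired 5'/3' halves of equal length
_Geometry = tuple[tuple[str, int], ...]


def _segments(
    topology: Topology, kd: int, ld: int, ka: int, v: int, kt: int, lt: int,
    c1: int, c2: int, aa: int, acl: int,
) -> _Geometry:
    if topology is Topology.CLOVERLEAF:
        return (
            ("aa5", aa), ("d5", kd), ("dloop", ld), ("d3", kd),
            ("ac5", ka), ("acloop", acl), ("ac3", ka),
            ("vloop", v), ("t5", kt), ("tloop", lt), ("t3", kt), ("aa3", aa),
        )
    if topology is Topology.D_ARMLESS:
        return (
            ("aa5", aa), ("connector", c1),
            ("ac5", ka), ("acloop", acl), ("ac3", ka),
            ("vloop", v), ("t5", kt), ("tloop", lt), ("t3", kt), ("aa3", aa),
        )
    if topology is Topology.T_ARMLESS:
        return (
            ("aa5", aa), ("d5", kd), ("dloop", ld), ("d3", kd),
            ("ac5", ka), ("acloop", acl), ("ac3", ka),
            ("connector", c2), ("aa3", aa),
        )
    return (
        ("aa5", aa), ("connector", c1),
        ("ac5", ka), ("acloop", acl), ("ac3", ka),
        ("connector2", c2), ("aa3", aa),
    )


def _rng(pair: tuple[int, int]) -> range:
    return range(pair[0], pair[1] + 1)


@lru_cache(maxsize=8)
def _geometry_table(constraints: FoldConstraints):
    """All geometries within range windows, with precomputed prefix/total.

    Returns a list of (topology, geometry, prefix_to_loop, total) where
    ``prefix_to_loop`` is the number of nucleotides before the anticodon loop.
    """
    out = []
    aa, acl = constraints.aa_stem_len, constraints.ac_loop_len
    for topology in Topology:
        kds = _rng(constraints.d_stem_len) if topology in (Topology.CLOVERLEAF, Topology.T_ARMLESS) else [0]
        lds = _rng(constraints.d_loop_len) if topology in (Topology.CLOVERLEAF, Topology.T_ARMLESS) else [0]
        kts = _rng(constraints.t_stem_len) if topology in (Topology.CLOVERLEAF, Topology.D_ARMLESS) else [0]
        lts = _rng(constraints.t_loop_len) if topology in (Topology.CLOVERLEAF, Topology.D_ARMLESS) else [0]
        vs = _rng(constraints.variable_loop_len) if topology in (Topology.CLOVERLEAF, Topology.D_ARMLESS) else [0]
        conn = (
            _rng(constraints.armless_connector_len)
            if topology is Topology.ARMLESS
            else _rng(constraints.connector_len)
        )
        c1s = conn if topology in (Topology.D_ARMLESS, Topology.ARMLESS) else [0]
        c2s = conn if topology in (Topology.T_ARMLESS, Topology.ARMLESS) else [0]
        for kd in kds:
            for ld in lds:
                for ka in _rng(constraints.ac_stem_len):
                    for v in vs:
                        for kt in kts:
                            for lt in lts:
                                for c1 in c1s:
                                    for c2 in c2s:
                                        geom = _segments(
                                            topology, kd, ld, ka, v, kt, lt, c1, c2, aa, acl
                                        )
                                        total = sum(n for _, n in geom)
                                        if not (
                                            constraints.total_len[0]
                                            <= total
                                            <= constraints.total_len[1]
                                        ):
                                            continue
                                        prefix = 0
                                        for name, n in geom:
                                            if name == "acloop":
                                                break
                                            prefix += n
                                        out.append((topology, geom, prefix, total))
    return out


def anchor_flank_minima(constraints: FoldConstraints) -> tuple[int, int]:
    """Minimum nt required before/after an anticodon for any geometry."""
    table = _geometry_table(constraints)
    min_pre = min(p + 2 for _, _, p, _ in table)
    min_suf = min(t - p - 2 - 3 for _, _, p, t in table)
    return min_pre, min_suf


def _count_stem_mismatches(seq: str, s5: int, e5: int, s3: int, e3: int, wobble: bool) -> int:
    n = e5 - s5
    count = 0
    for i in range(n):
        a, b = seq[s5 + i], seq[e3 - 1 - i]
        pair = (a, b)
        if pair not in _WC and not (wobble and pair in _WOBBLE):
            count += 1
    return count


_STEMS = (("aa", "aa5", "aa3"), ("d", "d5", "d3"), ("ac", "ac5", "ac3"), ("t", "t5", "t3"))


def _build_structure(
    seq: str, topology: Topology, geom: _Geometry, offset: int,
    constraints: FoldConstraints, weights: dict[str, float],
    memo: dict | None = None,
) -> TrnaStructure | None:
    """Tile ``seq[offset:]`` with ``geom``; None when a mismatch cap is hit."""
    arms = []
    pos = offset
    for name, n in geom:
        arms.append((name, pos, pos + n))
        pos += n
    index = {name: (s, e) for name, s, e in arms}
    caps = constraints.caps
    mism = []
    for stem, five, three in _STEMS:
        if five not in index:
            continue
        s5, e5 = index[five]
        s3, e3 = index[three]
        key = (s5, e5, s3, e3)
        if memo is not None and key in memo:
            count = memo[key]
        else:
            count = _count_stem_mismatches(seq, s5, e5, s3, e3, constraints.allow_wobble)
            if memo is not None:
                memo[key] = count
        if count > caps.get(stem, 0):
            return None
        mism.append((stem, count))
    rel_arms = tuple((name, s - offset, e - offset) for name, s, e in arms)
    mismatches = tuple(mism)
    penalty = sum(weights[stem] * c for stem, c in mismatches) + weights[
        "missing_arm"
    ] * topology.missing_arms
    loop_s = index["acloop"][0]
    return TrnaStructure(
        sequence=seq[offset : pos],
        topology=topology,
        arms=rel_arms,
        mismatches=mismatches,
        anticodon=seq[loop_s + 2 : loop_s + 5],
        ac_offset=loop_s + 2 - offset,
        structure_penalty=penalty,
    )


def _sort_key(s: TrnaStructure):
    return (
        s.structure_penalty,
        s.topology.missing_arms,
        sum(c for _, c in s.mismatches),
        s.topology.value,
        s.segment_lengths(),
    )


def fold_around_anticodon(
    seq: str,
    ac_offset: int,
    constraints: FoldConstraints | None = None,
    weights: dict[str, float] | None = None,
) -> list[TrnaStructure]:
    """Fold the whole of ``seq`` with its anticodon at ``ac_offset``.

    Enumerates every geometry (topology x segment lengths) that tiles the
    sequence exactly, places the anticodon at loop positions 3-5, and keeps
    those whose per-stem mismatch counts are all within the caps.  The result
    is sorted by ascending structure penalty with deterministic tie-breaks
    (fewer missing arms, fewer total mismatches, lexicographic geometry).
    """
    constraints = constraints or FoldConstraints()
    weights = weights or DEFAULT_PENALTY_WEIGHTS
    seq = seq.upper().replace("U", "T")
    if not 0 <= ac_offset <= len(seq) - 3:
        raise ValueError(f"anticodon offset {ac_offset} outside sequence of {len(seq)} nt")
    results = []
    memo: dict = {}
    for topology, geom, prefix, total in _geometry_table(constraints):
        if total != len(seq) or prefix + 2 != ac_offset:
            continue
        s = _build_structure(seq, topology, geom, 0, constraints, weights, memo)
        if s is not None:
            results.append(s)
    results.sort(key=_sort_key)
    return results


def fold_at_anchor(
    seq: str,
    anchor: int,
    constraints: FoldConstraints | None = None,
    weights: dict[str, float] | None = None,
) -> list[tuple[int, int, TrnaStructure]]:
    """Fold candidate sub-intervals of ``seq`` whose anticodon starts at ``anchor``.

    Unlike :func:`fold_around_anticodon`, the candidate gene boundaries are
    free: every geometry that fits inside ``seq`` around the anchor yields a
    ``(start, end, structure)`` triple.  Used by the gap scanner, where only
    the anticodon position is known.
    """
    constraints = constraints or FoldConstraints()
    weights = weights or DEFAULT_PENALTY_WEIGHTS
    seq = seq.upper().replace("U", "T")
    results = []
    memo: dict = {}
    for topology, geom, prefix, total in _geometry_table(constraints):
        start = anchor - prefix - 2
        end = start + total
        if start < 0 or end > len(seq):
            continue
        s = _build_structure(seq, topology, geom, start, constraints, weights, memo)
        if s is not None:
            results.append((start, end, s))
    results.sort(key=lambda t: (_sort_key(t[2]), t[0]))
    return results


def structure_penalty(
    s: TrnaStructure, weights: dict[str, float] | None = None
) -> float:
    """Penalty = sum(stem weight x mismatches) + weight x missing arms.

    Zero for a perfect cloverleaf; deterministic.
    """
    w = weights or DEFAULT_PENALTY_WEIGHTS
    return (
        sum(w[stem] * c for stem, c in s.mismatches)
        + w["missing_arm"] * s.topology.missing_arms
    )


def max_penalty(
    constraints: FoldConstraints, weights: dict[str, float] | None = None
) -> float:
    """Largest penalty any in-cap structure can carry (normalization constant)."""
    w = weights or DEFAULT_PENALTY_WEIGHTS
    caps = constraints.caps
    return sum(w[stem] * cap for stem, cap in caps.items()) + w["missing_arm"] * 2
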