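"""Independent brute-force enumerator for constrained tRNA folding.

Deliberately written from scratch, with its own pairing table and its own
per-topology nested loops, so it can serve as an oracle for the package's
geometry enumerator.  Only shares the *definitions*: AA-stem 7 bp, 7 nt
anticodon loop with the anticodon at positions 3-5, inclusive length windows,
per-stem mismatch caps, G-U wobble.
"""

from __future__ import annotations

PAIRS = {"AT", "TA", "GC", "CG"}
WOBBLE = {"GT", "TG"}


def _stem_mismatches(five: str, three: str, wobble: bool) -> int:
    n = 0
    for a, b in zip(five, three[::-1]):
        if a + b in PAIRS:
            continue
        if wobble and a + b in WOBBLE:
            continue
        n += 1
    return n


def enumerate_structures(seq: str, ac_offset: int, c) -> set:
    """All in-cap geometry assignments of ``seq`` around its anticodon.

    ``c`` is a FoldConstraints-like object.  Returns a set of hashable
    descriptors: (topology name, ((segment, length), ...), ((stem, count), ...)).
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    out = set()
    caps = dict(c.max_mismatch)
    if not (c.total_len[0] <= L <= c.total_len[1]):
        return out
    aa = c.aa_stem_len
    acl = c.ac_loop_len

    def try_geometry(topology: str, segs: list[tuple[str, int]]):
        if sum(n for _, n in segs) != L:
            return
        pos = 0
        coords = {}
        for name, n in segs:
            coords[name] = (pos, pos + n)
            pos += n
        loop_start = coords["acloop"][0]
        if loop_start + 2 != ac_offset:
            return
        counts = []
        for stem in ("aa", "d", "ac", "t"):
            if stem + "5" not in coords:
                continue
            s5, e5 = coords[stem + "5"]
            s3, e3 = coords[stem + "3"]
            m = _stem_mismatches(seq[s5:e5], seq[s3:e3], c.allow_wobble)
            if m > caps[stem]:
                return
            counts.append((stem, m))
        out.add((topology, tuple(segs), tuple(sorted(counts))))

    ka_range = range(c.ac_stem_len[0], c.ac_stem_len[1] + 1)
    kd_range = range(c.d_stem_len[0], c.d_stem_len[1] + 1)
    ld_range = range(c.d_loop_len[0], c.d_loop_len[1] + 1)
    kt_range = range(c.t_stem_len[0], c.t_stem_len[1] + 1)
    lt_range = range(c.t_loop_len[0], c.t_loop_len[1] + 1)
    v_range = range(c.variable_loop_len[0], c.variable_loop_len[1] + 1)
    c_range = range(c.connector_len[0], c.connector_len[1] + 1)
    c_arm = range(c.armless_connector_len[0], c.armless_connector_len[1] + 1)

    for ka in ka_range:
        for kd in kd_range:
            for ld in ld_range:
                for kt in kt_range:
                    for lt in lt_range:
                        for v in v_range:
                            try_geometry(
                                "CLOVERLEAF",
                                [("aa5", aa), ("d5", kd), ("dloop", ld), ("d3", kd),
                                 ("ac5", ka), ("acloop", acl), ("ac3", ka), ("vloop", v),
                                 ("t5", kt), ("tloop", lt), ("t3", kt), ("aa3", aa)],
                            )
        for kt in kt_range:
            for lt in lt_range:
                for v in v_range:
                    for c1 in c_range:
                        try_geometry(
                            "D_ARMLESS",
                            [("aa5", aa), ("connector", c1), ("ac5", ka), ("acloop", acl),
                             ("ac3", ka), ("vloop", v), ("t5", kt), ("tloop", lt),
                             ("t3", kt), ("aa3", aa)],
                        )
        for kd in kd_range:
            for ld in ld_range:
                for c2 in c_range:
                    try_geometry(
                        "T_ARMLESS",
                        [("aa5", aa), ("d5", kd), ("dloop", ld), ("d3", kd), ("ac5", ka),
                         ("acloop", acl), ("ac3", ka), ("connector", c2), ("aa3", aa)],
                    )
        for c1 in c_arm:
            for c2 in c_arm:
                try_geometry(
                    "ARMLESS",
                    [("aa5", aa), ("connector", c1), ("ac5", ka), ("acloop", acl),
                     ("ac3", ka), ("connector2", c2), ("aa3", aa)],
                )
    return out


def descriptor_set(structures) -> set:
    """The same descriptors for the package's fold output."""
    return {
        (s.topology.value, s.segment_lengths(), tuple(sorted(s.mismatches)))
        for s in structures
    }
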