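"""Codon usage and RSCU for mitochondrial protein-coding genes.

Codons of the 13 PCGs are counted under the invertebrate mitochondrial
genetic code (translation table 5).  Relative synonymous codon usage for a
codon *i* in a synonymous family of size *k* with counts *n* is

    RSCU_i = n_i * k / sum_j n_j

so within every used family the RSCU values sum to the family size.  Stop
codons are excluded from both RSCU and amino-acid percentages (tallied
separately); incomplete stops (a trailing ``T`` completed by polyadenylation,
typical before tRNA genes) are flagged and dropped from counting.  The
two-gene leucine and serine tRNA families are reported both pooled (L, S)
and split by identity (L1 = CUN, L2 = UUR, S1 = AGN, S2 = UCN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

from ._vocab import TRNA_IDENTITIES
from .genome_io import AnnotatedGenome

__all__ = [
    "GeneticCode",
    "CdsCodons",
    "CodonUsageTable",
    "extract_cds",
    "count_codons",
    "rscu",
    "aa_frequencies",
    "identity_family_counts",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid table with start and stop codon sets."""

    table_id: int = 5

    @property
    def _table(self):
        return CodonTable.unambiguous_dna_by_id[self.table_id]

    @property
    def forward(self) -> dict[str, str]:
        return dict(self._table.forward_table)

    @property
    def start_codons(self) -> frozenset[str]:
        return frozenset(self._table.start_codons)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(self._table.stop_codons)

    def translate(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]

    def family(self, codon: str) -> list[str]:
        """The synonymous family of a codon (all codons for its amino acid)."""
        aa = self.translate(codon)
        if aa == "*":
            return sorted(self.stop_codons)
        return sorted(c for c, a in self.forward.items() if a == aa)


#: codon sets of the split leucine/serine tRNA identities
_IDENTITY_CODONS_SPECIAL = {
    "trnL1": ("CTT", "CTC", "CTA", "CTG"),
    "trnL2": ("TTA", "TTG"),
    "trnS1": ("AGT", "AGC", "AGA", "AGG"),
    "trnS2": ("TCT", "TCC", "TCA", "TCG"),
}


def identity_of_codon(codon: str, code: GeneticCode | None = None) -> str | None:
    """tRNA identity serving a codon (``trnL1``/``trnL2`` etc. split)."""
    code = code or GeneticCode()
    aa = code.translate(codon)
    if aa == "*":
        return None
    for identity, codons in _IDENTITY_CODONS_SPECIAL.items():
        if codon in codons:
            return identity
    return f"trn{aa}"


@dataclass(frozen=True)
class CdsCodons:
    """Codons of one PCG, with stop bookkeeping."""

    gene: str
    codons: tuple[str, ...]  # coding codons, terminal stop excluded
    stop: str | None  # "TAA"/"TAG", "T" for an incomplete stop, None if absent
    incomplete_stop: bool
    warnings: tuple[str, ...] = ()


@dataclass
class CodonUsageTable:
    """Per-genome codon counts with optional RSCU annotation."""

    genome_id: str
    counts: dict[str, int] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)
    incomplete_stop_genes: tuple[str, ...] = ()
    rscu_values: dict[str, float] | None = None
    unused_families: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path, code: GeneticCode | None = None) -> None:
        code = code or GeneticCode()
        with Path(path).open("w") as fh:
            fh.write("codon\tamino_acid\tidentity\tcount\trscu\n")
            for codon in ALL_CODONS:
                if codon in code.stop_codons:
                    continue
                aa = code.translate(codon)
                identity = identity_of_codon(codon, code) or ""
                r = "" if self.rscu_values is None else f"{self.rscu_values[codon]:.4f}"
                fh.write(f"{codon}\t{aa}\t{identity}\t{self.counts.get(codon, 0)}\t{r}\n")


def extract_cds(ag: AnnotatedGenome, code: GeneticCode | None = None) -> list[CdsCodons]:
    """Strand-aware codon extraction for every annotated PCG.

    A CDS of length ``3n + 1`` ending in T is treated as carrying an
    incomplete stop codon (flagged, trailing T dropped); length ``3n + 2``
    draws a warning and is truncated.  A complete terminal TAA/TAG is removed
    from the coding codons and recorded in ``stop``.
    """
    code = code or GeneticCode()
    out = []
    for f in ag.pcgs():
        seq = f.sequence(ag.genome)
        warns: list[str] = []
        incomplete = False
        stop: str | None = None
        tail = len(seq) % 3
        if tail == 1:
            if seq.endswith("T"):
                incomplete = True
                stop = "T"
                seq = seq[:-1]
            else:
                warns.append(f"{f.name}: length mod 3 == 1 without trailing T; truncated")
                seq = seq[:-1]
        elif tail == 2:
            warns.append(f"{f.name}: CDS length mod 3 == 2; truncated")
            warnings.warn(warns[-1])
            seq = seq[:-2]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in code.stop_codons:
            stop = codons.pop()
        out.append(
            CdsCodons(
                gene=f.name,
                codons=tuple(codons),
                stop=stop,
                incomplete_stop=incomplete,
                warnings=tuple(warns),
            )
        )
    return out


def count_codons(ag: AnnotatedGenome, code: GeneticCode | None = None) -> CodonUsageTable:
    """Codon counts over all PCGs of a genome (stops tallied separately)."""
    code = code or GeneticCode()
    cds = extract_cds(ag, code)
    if not any(c.codons for c in cds):
        raise ValueError("no codons: genome has no annotated PCG codons")
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    incomplete = []
    for c in cds:
        for codon in c.codons:
            if codon in code.stop_codons:  # internal stop: count separately
                stops[codon] = stops.get(codon, 0) + 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
        if c.stop is not None:
            stops[c.stop] = stops.get(c.stop, 0) + 1
        if c.incomplete_stop:
            incomplete.append(c.gene)
    return CodonUsageTable(
        genome_id=ag.genome.id,
        counts=counts,
        stop_counts=stops,
        incomplete_stop_genes=tuple(incomplete),
    )


def rscu(table: CodonUsageTable, code: GeneticCode | None = None) -> CodonUsageTable:
    """Annotate a count table with RSCU values.

    Families with zero total get RSCU 0 for every member and are flagged as
    unused.
    """
    code = code or GeneticCode()
    values: dict[str, float] = {}
    unused: list[str] = []
    seen: set[str] = set()
    for codon in ALL_CODONS:
        if codon in code.stop_codons or codon in seen:
            continue
        fam = [c for c in code.family(codon) if c not in code.stop_codons]
        seen.update(fam)
        total = sum(table.counts.get(c, 0) for c in fam)
        if total == 0:
            unused.append(code.translate(codon))
            for c in fam:
                values[c] = 0.0
        else:
            k = len(fam)
            for c in fam:
                values[c] = table.counts.get(c, 0) * k / total
    table.rscu_values = values
    table.unused_families = tuple(sorted(set(unused)))
    return table


def aa_frequencies(
    table: CodonUsageTable, code: GeneticCode | None = None, split_leu_ser: bool = True
) -> dict[str, float]:
    """Percent of all non-stop codons per amino acid.

    With ``split_leu_ser`` the two-gene families are additionally reported by
    tRNA identity (keys ``L1``, ``L2``, ``S1``, ``S2``) next to the pooled
    ``L`` and ``S``.
    """
    code = code or GeneticCode()
    total = table.total
    if total == 0:
        raise ValueError("no codons")
    out: dict[str, float] = {}
    for codon, n in table.counts.items():
        aa = code.translate(codon)
        out[aa] = out.get(aa, 0.0) + n
    for identity, codons in _IDENTITY_CODONS_SPECIAL.items() if split_leu_ser else ():
        key = identity[3:]  # L1, L2, S1, S2
        out[key] = sum(table.counts.get(c, 0) for c in codons)
    return {k: 100.0 * v / total for k, v in sorted(out.items())}


def identity_family_counts(
    table: CodonUsageTable, code: GeneticCode | None = None
) -> dict[str, int]:
    """Total codon count served by each of the 22 tRNA identities.

    On a complete mitochondrial annotation every family is expected to be
    non-zero — the codon-usage argument against true tRNA gene loss.
    """
    code = code or GeneticCode()
    out = {identity: 0 for identity in TRNA_IDENTITIES}
    for codon, n in table.counts.items():
        identity = identity_of_codon(codon, code)
        if identity is not None:
            out[identity] += n
    return out
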