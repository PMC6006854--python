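"""Genome and annotation I/O for circular mitochondrial genomes.

Internal coordinates are 0-based half-open on the forward strand; features
that wrap the origin of a circular genome keep ``end > length`` and are
normalized modulo the genome length on access.  Reports use the 1-based
inclusive GenBank dialect.  Strands are labelled J (majority-coding) and N
(minority): J is the strand carrying most annotated genes, ties broken by the
strand of ``cox1``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._vocab import (
    CANONICAL_GENES,
    PCGS,
    RRNAS,
    TRNA_IDENTITIES,
    normalize_gene_name,
    revcomp,
)

__all__ = [
    "Genome",
    "GeneFeature",
    "AnnotatedGenome",
    "GapRegion",
    "GeneOrderType",
    "GENE_ORDER_TEMPLATES",
    "read_genbank",
    "read_fasta",
    "write_genbank",
    "extract_gaps",
    "classify_gene_order",
    "write_feature_table",
    "read_feature_table",
    "write_gff3",
]

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for unparseable or malformed input files."""


@dataclass(frozen=True)
class Genome:
    """A (typically circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise FormatError("empty genome sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"non-ACGT bases after normalization: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand subsequence; wraps the origin when circular."""
        L = self.length
        if end <= L and 0 <= start <= end:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear genome of {L} nt")
        length = end - start
        if length < 0:
            raise IndexError("end before start")
        start %= L
        out = []
        pos = start
        remaining = length
        while remaining > 0:
            take = min(remaining, L - pos)
            out.append(self.sequence[pos : pos + take])
            remaining -= take
            pos = (pos + take) % L
        return "".join(out)


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene feature on the forward coordinate system."""

    name: str
    kind: str  # PCG | rRNA | tRNA | CR | other
    strand: str  # J | N
    start: int
    end: int  # half-open; may exceed genome length for origin-wrapping features
    anticodon: str | None = None
    raw_name: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.name}: empty or inverted interval")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Genome) -> str:
        """Gene sequence read 5'->3' on its own strand."""
        s = genome.fetch(self.start, self.end)
        return revcomp(s) if self.strand == "N" else s


def _kind_of(name: str) -> str:
    if name in PCGS:
        return "PCG"
    if name in RRNAS:
        return "rRNA"
    if name in TRNA_IDENTITIES:
        return "tRNA"
    if name == "CR":
        return "CR"
    return "other"


@dataclass
class AnnotatedGenome:
    """A genome with its ordered, strand-aware gene features."""

    genome: Genome
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))
        L = self.genome.length
        for f in self.features:
            if not 0 <= f.start < L:
                raise ValueError(f"{f.name}: start {f.start} outside [0, {L})")
        names = [f.name for f in self.features if f.kind != "CR" and f.kind != "other"]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate gene annotations: {sorted(dup)}")

    def get(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def trnas(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "tRNA"]

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "PCG"]


@dataclass(frozen=True)
class GapRegion:
    """A maximal unannotated inter-gene interval (may wrap the origin)."""

    start: int
    end: int
    left_flank: str
    right_flank: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Genome) -> str:
        return genome.fetch(self.start, self.end)


# ---------------------------------------------------------------------------
# GenBank / FASTA reading
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop")


def _qualifier_name(feat) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _qualifier_anticodon(feat) -> str | None:
    import re

    q = feat.qualifiers
    if "anticodon" in q:
        m = re.search(r"seq[:=]\s*([acgut]{3})", str(q["anticodon"][0]), re.I)
        if m:
            return m.group(1).upper().replace("U", "T")
        m = re.fullmatch(r"[acgut]{3}", str(q["anticodon"][0]).strip(), re.I)
        if m:
            return m.group(0).upper().replace("U", "T")
    if "note" in q:
        m = re.search(r"anticodon[:\s]*([acgut]{3})", str(q["note"][0]), re.I)
        if m:
            return m.group(1).upper().replace("U", "T")
    return None


def _location_interval(loc, length: int) -> tuple[int, int]:
    """Map a (possibly origin-spanning compound) location to start/end."""
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(loc.start), int(loc.end)
    # origin-wrapping join(a..L, 1..b): the high-coordinate part comes first
    first = max(parts, key=lambda p: int(p.start))
    last = min(parts, key=lambda p: int(p.start))
    if int(first.end) == length and int(last.start) == 0:
        return int(first.start), length + int(last.end)
    # non-wrapping compound (e.g. annotated join); use the envelope
    return int(parts[0].start), int(parts[-1].end)


def relabel_strands(features: list[GeneFeature]) -> list[GeneFeature]:
    """Assign J to the majority-gene strand (ties: the strand of cox1)."""
    genes = [f for f in features if f.kind in ("PCG", "rRNA", "tRNA")]
    n_j = sum(1 for f in genes if f.strand == "J")
    n_n = len(genes) - n_j
    flip = n_n > n_j
    if n_n == n_j:
        cox1 = next((f for f in genes if f.name == "cox1"), None)
        flip = cox1 is not None and cox1.strand == "N"
    if not flip:
        return features
    swap = {"J": "N", "N": "J"}
    return [replace(f, strand=swap[f.strand]) for f in features]


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene and product synonyms are normalized onto the controlled vocabulary
    (e.g. ``tRNA-Ser(UCN)`` -> ``trnS2``); unmappable names are kept verbatim
    with a warning.  The forward strand of the record is provisionally called
    J and relabelled afterwards so that J carries the majority of genes.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) - _VALID_BASES:
        seq = "".join(b if b in _VALID_BASES else "A" for b in seq)
        warnings.warn(f"{path}: ambiguity codes mapped to A")
    circular = record.annotations.get("topology", "circular") == "circular"
    genome = Genome(id=record.id or record.name, sequence=seq, circular=circular)

    feats = [f for f in record.features if f.type in _FEATURE_TYPES]
    if not feats:
        feats = [f for f in record.features if f.type == "gene"]
    out: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    for f in feats:
        raw = _qualifier_name(f)
        if raw is None:
            continue
        anticodon = _qualifier_anticodon(f)
        name = normalize_gene_name(raw, anticodon=anticodon)
        if f.type == "D-loop" or (name is None and "control" in raw.lower()):
            name = "CR"
        if name is None:
            warnings.warn(f"{path}: unmappable gene name {raw!r}; kept verbatim")
            name = raw
        start, end = _location_interval(f.location, genome.length)
        key = (name, start % genome.length, end)
        if key in seen:
            continue
        seen.add(key)
        strand = "N" if f.location.strand == -1 else "J"
        out.append(
            GeneFeature(
                name=name,
                kind=_kind_of(name),
                strand=strand,
                start=start % genome.length,
                end=end if end > start % genome.length else end + genome.length,
                anticodon=anticodon,
                raw_name=raw,
            )
        )
    return AnnotatedGenome(genome=genome, features=relabel_strands(out))


def read_fasta(path: str | Path, circular: bool = True) -> Genome:
    """Read a single-sequence FASTA file."""
    record = SeqIO.read(str(path), "fasta")
    seq = str(record.seq).upper()
    seq = "".join(b if b in _VALID_BASES else "A" for b in seq)
    return Genome(id=record.id, sequence=seq, circular=circular)


def write_genbank(ag: AnnotatedGenome, path: str | Path) -> None:
    """Write an annotated genome as a GenBank flat file."""
    rec = SeqRecord(
        Seq(ag.genome.sequence),
        id=ag.genome.id,
        name=ag.genome.id[:16].replace(".", "_"),
        description="mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if ag.genome.circular else "linear",
        },
    )
    L = ag.genome.length
    for f in ag.features:
        strand = -1 if f.strand == "N" else 1
        if f.end <= L:
            loc = FeatureLocation(f.start, f.end, strand=strand)
        else:
            loc = FeatureLocation(f.start, L, strand=strand) + FeatureLocation(
                0, f.end - L, strand=strand
            )
        ftype = {"PCG": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}.get(f.kind, "misc_feature")
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        if f.kind == "CR":
            quals["note"] = ["putative control region"]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Gap extraction
# ---------------------------------------------------------------------------


def extract_gaps(
    ag: AnnotatedGenome,
    min_len: int = 46,
    max_len: int = 215,
    treat_cr_as_gap: bool = True,
) -> list[GapRegion]:
    """Maximal unannotated intervals with ``min_len <= length <= max_len``.

    Coverage is computed position-wise on the circle, so overlapping
    annotations simply truncate the gap.  With ``treat_cr_as_gap`` (default),
    control-region features do not mask sequence, which keeps non-coding
    region detection reproducible from the gene annotation alone.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    g = ag.genome
    L = g.length
    covered = np.zeros(L, dtype=bool)
    owner = np.full(L, -1, dtype=int)
    masking = [
        f
        for f in ag.features
        if not (f.kind == "CR" and treat_cr_as_gap) and f.kind != "other"
    ]
    for i, f in enumerate(masking):
        idx = np.arange(f.start, f.end) % L
        covered[idx] = True
        owner[idx[owner[idx] < 0]] = i  # first annotation wins
    if covered.all():
        return []
    if not covered.any():
        return []

    # maximal runs of uncovered positions on the circle
    uncov = ~covered
    # rotate so position 0 is covered, then find runs linearly
    anchor = int(np.argmax(covered))
    rot = np.roll(uncov, -anchor)
    diffs = np.diff(rot.astype(int))
    starts = list((np.where(diffs == 1)[0] + 1))
    ends = list((np.where(diffs == -1)[0] + 1))
    if rot[0]:
        starts = [0] + starts
    if rot[-1]:
        ends = ends + [L]
    gaps: list[GapRegion] = []
    for s_rot, e_rot in zip(starts, ends):
        s = int((s_rot + anchor) % L)
        length = int(e_rot - s_rot)
        e = s + length
        if not (min_len <= length <= max_len):
            continue
        left = masking[owner[(s - 1) % L]].name if owner[(s - 1) % L] >= 0 else ""
        right = masking[owner[e % L]].name if owner[e % L] >= 0 else ""
        gaps.append(GapRegion(start=s, end=e, left_flank=left, right_flank=right))
    gaps.sort(key=lambda r: r.start)
    return gaps


def noncoding_regions(ag: AnnotatedGenome, floor: int = 100) -> list[GapRegion]:
    """All non-coding regions of at least ``floor`` nt (no upper window)."""
    g = ag.genome
    return [
        r
        for r in extract_gaps(ag, min_len=1, max_len=g.length, treat_cr_as_gap=True)
        if r.length >= floor
    ]


# ---------------------------------------------------------------------------
# Gene-order typing
# ---------------------------------------------------------------------------

GeneOrderType = str  # "I".."V" or "novel"

# Five reference arrangements of the 37 mt genes of sarcoptiform mites.
# Type I is the arrangement shared by most sequenced species; II-IV are the
# single translocation/inversion variants described for Histiostoma-,
# Tyrophagus- and related lineages; Type V is the strongly shuffled oribatid
# arrangement.  Entries are (gene, strand) clockwise; CR placement is carried
# for genome simulation but ignored by the classifier.
GENE_ORDER_TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    "I": (
        ("cox1", "J"), ("trnD", "J"), ("trnE", "J"), ("cox2", "J"),
        ("trnK", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
        ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"),
        ("trnN", "J"), ("trnT", "J"), ("nad4L", "N"), ("nad4", "N"),
        ("trnW", "J"), ("trnH", "N"), ("nad5", "N"), ("trnL1", "N"),
        ("cob", "J"), ("trnS2", "J"), ("nad6", "J"), ("trnC", "J"),
        ("nad1", "N"), ("trnL2", "N"), ("rrnL", "N"), ("trnV", "N"),
        ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
        ("trnY", "J"), ("rrnS", "N"), ("trnF", "J"), ("CR", "J"),
        ("trnS1", "J"), ("trnP", "J"),
    ),
    # Type I with trnV, trnW and trnF translocated
    "II": (
        ("cox1", "J"), ("trnD", "J"), ("trnE", "J"), ("cox2", "J"),
        ("trnK", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
        ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"),
        ("trnN", "J"), ("trnT", "J"), ("nad4L", "N"), ("nad4", "N"),
        ("trnH", "N"), ("nad5", "N"), ("trnL1", "N"),
        ("cob", "J"), ("trnS2", "J"), ("nad6", "J"), ("trnC", "J"),
        ("trnW", "J"),
        ("nad1", "N"), ("trnL2", "N"), ("rrnL", "N"),
        ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
        ("trnY", "J"), ("trnF", "J"), ("rrnS", "N"),
        ("trnS1", "J"), ("trnP", "J"), ("trnV", "J"),
    ),
    # Type I with trnS2, trnC, trnF and trnA translocated
    "III": (
        ("cox1", "J"), ("trnD", "J"), ("trnS2", "J"), ("trnE", "J"),
        ("cox2", "J"), ("trnK", "J"), ("atp8", "J"), ("atp6", "J"),
        ("cox3", "J"), ("trnG", "J"), ("nad3", "J"), ("trnC", "J"),
        ("trnR", "J"), ("trnN", "J"), ("trnT", "J"), ("nad4L", "N"),
        ("nad4", "N"), ("trnW", "J"), ("trnH", "N"), ("nad5", "N"),
        ("trnL1", "N"), ("cob", "J"), ("nad6", "J"), ("nad1", "N"),
        ("trnL2", "N"), ("rrnL", "N"), ("trnV", "N"), ("trnI", "J"),
        ("trnQ", "N"), ("trnM", "J"), ("trnF", "J"), ("nad2", "J"),
        ("trnY", "J"), ("rrnS", "N"), ("CR", "J"), ("trnS1", "J"),
        ("trnP", "J"), ("trnA", "J"),
    ),
    # Type I with trnV translocated, trnI inverted, and trnF/trnS1/trnQ absent
    "IV": (
        ("cox1", "J"), ("trnD", "J"), ("trnE", "J"), ("cox2", "J"),
        ("trnK", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
        ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"),
        ("trnN", "J"), ("trnT", "J"), ("nad4L", "N"), ("nad4", "N"),
        ("trnW", "J"), ("trnH", "N"), ("nad5", "N"), ("trnL1", "N"),
        ("cob", "J"), ("trnS2", "J"), ("nad6", "J"), ("trnC", "J"),
        ("nad1", "N"), ("trnL2", "N"), ("rrnL", "N"), ("trnI", "N"),
        ("trnM", "J"), ("nad2", "J"), ("trnV", "J"), ("trnY", "J"),
        ("rrnS", "N"), ("CR", "J"), ("trnP", "J"),
    ),
    # strongly rearranged arrangement
    "V": (
        ("cox1", "J"), ("cox2", "J"), ("trnD", "J"), ("atp8", "J"),
        ("atp6", "J"), ("trnC", "J"), ("cox3", "J"), ("trnK", "J"),
        ("nad3", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
        ("trnH", "N"), ("nad4", "N"), ("nad4L", "N"), ("trnT", "J"),
        ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
        ("trnW", "J"), ("nad1", "N"), ("trnL2", "N"), ("trnL1", "N"),
        ("rrnL", "N"), ("trnV", "N"), ("rrnS", "N"), ("CR", "J"),
        ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
        ("trnS1", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
        ("trnY", "J"), ("trnG", "J"),
    ),
}


class ClassificationError(ValueError):
    """Raised when too few canonical genes are annotated to type the order."""


def _signed_order(pairs: list[tuple[str, str]], keep: set[str]) -> list[tuple[str, str]]:
    return [(n, s) for n, s in pairs if n in keep]


def _rotations_equal(a: list[tuple[str, str]], b: list[tuple[str, str]]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    for shift in range(len(a)):
        if a[shift:] + a[:shift] == b:
            return True
    return False


def classify_gene_order(ag: AnnotatedGenome, min_genes: int = 30) -> GeneOrderType:
    """Type the circular, strand-signed gene order against the five templates.

    Comparison is invariant to the rotation of the origin; genes missing from
    either the query or a template are skipped in both before comparing.
    Returns ``"novel"`` when no template matches.
    """
    query = [
        (f.name, f.strand)
        for f in ag.features
        if f.name in CANONICAL_GENES and f.kind in ("PCG", "rRNA", "tRNA")
    ]
    if len(query) < min_genes:
        raise ClassificationError(
            f"only {len(query)} of 37 canonical genes annotated (need >= {min_genes})"
        )
    qnames = {n for n, _ in query}
    for type_name, template in GENE_ORDER_TEMPLATES.items():
        tpl = [(n, s) for n, s in template if n != "CR"]
        common = qnames & {n for n, _ in tpl}
        a = _signed_order(query, common)
        b = _signed_order(tpl, common)
        if _rotations_equal(a, b):
            return type_name
    return "novel"


# ---------------------------------------------------------------------------
# Feature table / GFF3 output
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "gene", "kind", "strand", "start", "end", "length",
    "anticodon", "start_codon", "stop_codon",
]


def write_feature_table(ag: AnnotatedGenome, path: str | Path) -> None:
    """Write a TSV feature table (1-based inclusive coordinates).

    For origin-wrapping features ``end`` exceeds the genome length, mirroring
    the internal representation so that the table is lossless.  A GFF3 file
    is emitted next to the TSV (same stem, ``.gff3`` suffix).
    """
    path = Path(path)
    g = ag.genome
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["# genome", g.id, str(g.length), "circular" if g.circular else "linear"])
        w.writerow(_TABLE_COLUMNS)
        for f in ag.features:
            start_codon = stop_codon = ""
            if f.kind == "PCG":
                s = f.sequence(g)
                start_codon = s[:3]
                tail = len(s) % 3
                if tail == 1 and s.endswith("T"):
                    stop_codon = "T(incomplete)"
                elif len(s) >= 3:
                    stop_codon = s[-3:]
            w.writerow(
                [
                    f.name, f.kind, f.strand, f.start + 1, f.end, f.length,
                    f.anticodon or "", start_codon, stop_codon,
                ]
            )
    write_gff3(ag, path.with_suffix(".gff3"))


def read_feature_table(path: str | Path, genome: Genome) -> AnnotatedGenome:
    """Rebuild an :class:`AnnotatedGenome` from a feature-table TSV."""
    features = []
    with Path(path).open() as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header_idx = next(i for i, r in enumerate(rows) if r and r[0] == "gene")
    for row in rows[header_idx + 1 :]:
        if not row or row[0].startswith("#"):
            continue
        name, kind, strand, start, end = row[0], row[1], row[2], int(row[3]), int(row[4])
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                strand=strand,
                start=start - 1,
                end=end,
                anticodon=row[6] or None,
            )
        )
    return AnnotatedGenome(genome=genome, features=features)


def write_gff3(ag: AnnotatedGenome, path: str | Path) -> None:
    """GFF3 output (columns 4/5 1-based inclusive, end clipped mod length)."""
    g = ag.genome
    type_map = {"PCG": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "CR": "region"}
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
        for f in ag.features:
            strand = "-" if f.strand == "N" else "+"
            attrs = f"ID={f.name};Name={f.name}"
            if f.anticodon:
                attrs += f";anticodon={f.anticodon}"
            end = f.end if f.end <= g.length else g.length  # GFF has no wrap
            fh.write(
                "\t".join(
                    [
                        g.id, "mitotrna", type_map.get(f.kind, "region"),
                        str(f.start + 1), str(end), ".", strand, ".", attrs,
                    ]
                )
                + "\n"
            )
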