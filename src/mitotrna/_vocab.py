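"""Controlled vocabulary for mitochondrial genes of sarcoptiform mites.

Canonical names follow the compact mitogenomics convention: 13 protein-coding
genes (PCGs), two rRNAs, 22 tRNAs (``trnX`` with the two-gene leucine and
serine families split as ``trnL1``/``trnL2`` and ``trnS1``/``trnS2``), and the
control region ``CR``.  The leucine/serine split follows tRNA identity:
L1 decodes CUN codons (anticodon UAG), L2 decodes UUR (UAA); S1 decodes AGN
(GCU), S2 decodes UCN (UGA).
"""

from __future__ import annotations

import re

PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

TRNA_IDENTITIES: tuple[str, ...] = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnV", "trnY",
)

CANONICAL_GENES: tuple[str, ...] = PCGS + RRNAS + TRNA_IDENTITIES

#: standard mt anticodons (DNA alphabet, 5'->3' as written in the gene)
STANDARD_ANTICODONS: dict[str, str] = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC",
    "trnC": "GCA", "trnE": "TTC", "trnQ": "TTG", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnK": "CTT", "trnL1": "TAG",
    "trnL2": "TAA", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS1": "GCT", "trnS2": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}

#: less common synonymous anticodons observed in sarcoptiform mites
ALTERNATIVE_ANTICODONS: dict[str, tuple[str, ...]] = {
    "trnE": ("CTC",),
    "trnI": ("AAT",),
    "trnC": ("ACA",),
    "trnQ": ("CTG",),
    "trnF": ("AAA",),
    "trnS1": ("ACT",),
}

#: single-letter amino-acid code per tRNA identity
IDENTITY_AA: dict[str, str] = {
    "trnA": "A", "trnR": "R", "trnN": "N", "trnD": "D", "trnC": "C",
    "trnE": "E", "trnQ": "Q", "trnG": "G", "trnH": "H", "trnI": "I",
    "trnL1": "L", "trnL2": "L", "trnK": "K", "trnM": "M", "trnF": "F",
    "trnP": "P", "trnS1": "S", "trnS2": "S", "trnT": "T", "trnW": "W",
    "trnV": "V", "trnY": "Y",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "glu": "E",
    "gln": "Q", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "val": "V", "tyr": "Y",
}

# synonyms keyed on lowercased, alphanumeric-only gene/product strings
_SYNONYMS: dict[str, str] = {
    "atp6": "atp6", "atpase6": "atp6", "atpsynthasef0subunit6": "atp6",
    "atpsynthasesubunit6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "atpsynthasef0subunit8": "atp8", "atpsynthasesubunit8": "atp8",
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cytochromecoxidasesubunit1": "cox1", "cytochromecoxidasesubuniti": "cox1",
    "cytochromeoxidasesubunit1": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cytochromecoxidasesubunit2": "cox2", "cytochromecoxidasesubunitii": "cox2",
    "cytochromeoxidasesubunit2": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytochromecoxidasesubunit3": "cox3", "cytochromecoxidasesubunitiii": "cox3",
    "cytochromeoxidasesubunit3": "cox3",
    "cob": "cob", "cytb": "cob", "cytochromeb": "cob",
    "cytochromebapoenzyme": "cob",
    "nad1": "nad1", "nd1": "nad1", "nadhdehydrogenasesubunit1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadhdehydrogenasesubunit2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadhdehydrogenasesubunit3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadhdehydrogenasesubunit4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nadhdehydrogenasesubunit4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5", "nadhdehydrogenasesubunit5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadhdehydrogenasesubunit6": "nad6",
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "lsu": "rrnL", "largesubunitribosomalrna": "rrnL", "16sribosomalrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    "ssu": "rrnS", "smallsubunitribosomalrna": "rrnS", "12sribosomalrna": "rrnS",
    "cr": "CR", "dloop": "CR", "controlregion": "CR", "atrichregion": "CR",
    "putativecontrolregion": "CR",
}

_TRNA_RE = re.compile(r"^trna?[-_ ]?([a-z]{3})\s*\(?([a-z]{3})?\)?$")

#: codon degeneracy groups that disambiguate two-gene tRNA families
_LEU_SER_BY_CODON_CLASS = {
    ("leu", "cun"): "trnL1", ("leu", "uur"): "trnL2",
    ("ser", "agn"): "trnS1", ("ser", "ucn"): "trnS2",
}


def _codon_class_from_anticodon(aa: str, triplet: str) -> str | None:
    """Degeneracy class from an *anticodon* triplet (UAA -> UUR, GCU -> AGN)."""
    t = triplet.lower().replace("t", "u")
    if aa == "leu":
        return "uur" if t.endswith("aa") else "cun"
    if aa == "ser":
        return "agn" if t.endswith("cu") else "ucn"
    return None


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str | None:
    """Map a GenBank gene/product string onto the controlled vocabulary.

    Returns ``None`` when the name cannot be mapped (the caller keeps the raw
    name and warns).  ``anticodon`` (DNA or RNA triplet) disambiguates the
    leucine and serine tRNA pairs when the name itself does not.
    """
    key = re.sub(r"[^a-z0-9]", "", raw.lower())
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # direct canonical hits such as "trnl1", "trns2"
    for name in CANONICAL_GENES:
        if key == name.lower():
            return name
    m = _TRNA_RE.match(raw.strip().lower().replace("transfer rna", "trna"))
    if m:
        aa3, codon = m.group(1), m.group(2)
        if aa3 not in _AA3_TO_1:
            return None
        aa1 = _AA3_TO_1[aa3]
        if aa3 in ("leu", "ser"):
            if codon is not None:
                cls = _codon_class_from_codon(aa3, codon)
            elif anticodon is not None:
                cls = _codon_class_from_anticodon(aa3, anticodon)
            else:
                return None
            if cls is None:
                return None
            return _LEU_SER_BY_CODON_CLASS[(aa3, cls)]
        return f"trn{aa1}"
    return None


def _codon_class_from_codon(aa: str, codon: str) -> str | None:
    """Class from a recognized-codon tag like ``tRNA-Ser(UCN)``."""
    c = codon.replace("t", "u")
    if aa == "leu":
        return "uur" if c.startswith("uu") else "cun"
    if aa == "ser":
        return "agn" if c.startswith("ag") else "ucn"
    return None


_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]
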