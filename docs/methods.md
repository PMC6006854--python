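# Methods

## The problem and the model

Mitochondrial tRNA genes in sarcoptiform mites can be so degenerate —
47–63 nt, missing the D- and/or T-arm, several mismatched stem positions,
occasionally a rare synonymous anticodon — that covariance-model finders
(tRNAscan-SE, ARWEN) miss them and the genes get reported as "lost".  The
package implements the alternative: a comparative search that assumes the
gene is still there, anchored by its anticodon, foldable into a truncated
tRNA shape, and recognizable by conservation of its anticodon arm among
related species.

A candidate gene is modelled as an exact tiling of a sequence interval into
segments.  Four topologies are allowed:

```
CLOVERLEAF  aa5 · d5 dloop d3 · ac5 acloop ac3 · vloop · t5 tloop t3 · aa3
D_ARMLESS   aa5 · connector   · ac5 acloop ac3 · vloop · t5 tloop t3 · aa3
T_ARMLESS   aa5 · d5 dloop d3 · ac5 acloop ac3 · connector           · aa3
ARMLESS     aa5 · connector   · ac5 acloop ac3 · connector           · aa3
```

The AA (aminoacyl-acceptor) stem is fixed at 7 bp and the anticodon loop at
7 nt with the anticodon at loop positions 3–5; this matches how the
published secondary structures are drawn, and deviations are absorbed by the
mismatch caps.  The two junction nucleotides of canonical tRNA numbering
(positions 8–9) are not modelled as a separate segment; the D-loop and
connector windows cover them.  Stem halves pair position-wise; a position is
a mismatch when the bases are neither Watson–Crick nor G–U wobble partners.
A geometry is kept only if every per-stem mismatch count is within its cap.
The CCA tail and acceptor discriminator are not modelled (genes, not
transcripts), and there is no thermodynamic folding — the point of the
method is precisely that these genes do not score well under generic models.

## Parameters

| parameter | default | meaning |
|---|---|---|
| gap window | 46–215 nt | inter-gene regions searched |
| AA-stem | 7 bp fixed | aminoacyl-acceptor stem |
| AC-stem | 4–5 bp | anticodon stem |
| D-stem / T-stem | 3–4 / 3–5 bp | arm stems (when present) |
| D-loop / T-loop | 3–10 nt | arm loops |
| variable loop | 1–6 nt | between AC- and T-arm |
| connector | 1–6 nt | replaces a missing arm |
| armless connectors | 1–12 nt | widened for the doubly truncated topology |
| total length | 45–75 nt | candidate gene length window |
| mismatch caps | AA 4, AC 2, D 1, T 1 | per-stem maxima |
| wobble | on | G–U counts as a bond |
| penalty weights | 1 per mismatch, 2 per missing arm | structure penalty |
| λ | 0.5 | weight of normalized penalty in the combined score |
| τ | 0.5 | acceptance threshold on the combined score |

The AA/AC caps are the degeneracy range actually observed in these genomes;
the D/T caps of 1 are an extrapolation (the observations quantify only the
AA and AC stems) and are exposed in configuration.  The armless connector
window is widened to 1–12 nt because with ≤ 6 nt connectors the armless
topology could never reach the 47–63 nt lengths such genes actually have
(maximum 7+6+5+7+5+6+7 = 43 nt).

λ and τ replace a human judgment ("overall secondary structure") with a
formula, so they are conventions, not measurements.  The penalty is
normalized by the largest value an in-cap structure can carry
(4+2+1+1 mismatches + 2 missing arms × 2 = 12 with default weights), so the
combined score lives on a fixed scale and τ is comparable across runs.

## Conservation scoring

The scored block is the anticodon arm + loop (AC-stem 5' half, 7 nt loop,
AC-stem 3' half; 15 or 17 nt).  It is aligned to each panel homolog anchored
at the anticodon with no gaps inside the block — the anticodon loop is the
conserved core these genes retain — and the score is the maximum over
homologs of the fraction of identical positions, over the candidate block
length.  Positions beyond a shorter homolog count as mismatches.

## Recovery driver

For each tRNA identity absent from the annotation: collect anticodon anchors
in every gap on both strands (standard anticodons, plus the six observed
alternatives — trnE CUC, trnI AAU, trnC ACA, trnQ CUG, trnF AAA, trnS1 ACU —
or every synonymous triplet in `all_synonymous` mode); fold each anchor with
free boundaries inside the gap; keep the lowest-penalty structure per anchor
(ties: fewer missing arms, fewer total mismatches, lexicographic geometry —
determinism matters more than any claim about which parse is "right");
score; report the best candidate with combined ≥ τ.  When two identities
claim overlapping intervals the higher combined score wins and the loser
falls back to its next-best non-overlapping candidate.  Candidates are
confined strictly inside gaps — no overlap with annotated genes.  An
identity with no passing candidate is reported as none; absences are data.

Boundary coordinates are intrinsically soft: equally-penalized geometries at
the same anchor can shift the gene ends, and reanalyses of the same real
loci have disagreed about AA-stem placement.  Reported genes carry a
boundary-uncertainty field (capped at ±2 nt) derived from the spread of
equally-scoring geometries, and the benchmark matches predictions to truth
by ≥ 50% reciprocal overlap rather than exact ends.

A consequence of free-boundary folding worth stating plainly: the mismatch
caps alone cannot veto a locus.  If a planted gene's AA-stem is destroyed
(6 of 7 positions unpaired), the enumerator can often re-place the stem a
few nucleotides away using flanking sequence — AT-rich sequence pairs at
roughly 0.4 per position — and the conserved anticodon arm still carries the
combined score over τ.  Structure caps localize the gene; conservation, not
structure, is what distinguishes a real locus from chance, and a locus whose
sequence is truly absent (the trnQ control) is the case that returns none.

## Control regions and gene order

By default annotated control regions do **not** mask sequence during gap
extraction, because CR annotations on deposited records are inferred and
inconsistent; NCR detection then depends only on the gene annotation.  The
two longest non-coding regions above a floor (default 100 nt) are reported
as putative CRs.  On synthetic genomes, whose CR is ground truth, the
benchmark masks it (`treat_cr_as_gap=False`).

Gene order is typed against five reference arrangements of the 37 genes
(Types I–V).  The concrete arrangements are the package's own reference set,
built to satisfy the published constraints relating the types (Type II =
Type I with trnV/trnW/trnF translocated, leaving non-coding gaps between
rrnL–trnI and nad4–trnH; Type III = Type I with trnS2/trnC/trnF/trnA
translocated; Type IV = trnV translocated, trnI inverted, trnF/trnS1/trnQ
absent; Type V strongly shuffled; J-strand gene counts 26 for Type I and 27
for Type II).  Comparison is on the circular, strand-signed gene sequence,
invariant to rotation, with genes missing from either side skipped in both;
anything else is `novel`.  Real deposited records may legitimately type as
`novel` against this reference set.

## Codon usage

Codons of the 13 PCGs are counted under translation table 5 (invertebrate
mitochondrial), strand-aware.  Incomplete stops (a trailing T before a tRNA
gene, completed by polyadenylation) are flagged and excluded; complete
terminal stops are tallied separately; stops are excluded from RSCU and
percentages.  ATN start codons are counted as their encoded amino acid, not
forced to Met.  RSCU families are the code's synonymous sets (Leu 6, Ser 8 —
AGN is serine in table 5); the two-gene families are additionally reported
split by tRNA identity (L1 = CUN, L2 = UUR, S1 = AGN, S2 = UCN).  Families
with zero total get RSCU 0 and an unused-family flag.

## The synthetic generator

`synthetic_data` builds circular genomes that emulate the data regime the
method was designed for: one of the five gene orders; 13 PCGs as random
codon strings drawn from a Phe/Ile/Met/Ser-heavy amino-acid mixture (defaults
sum to 1.0 with Phe at 0.13; ~3,000 codons at scale 1, nominal lengths
proportionate to real mt genes), ATN starts, TAA/TAG or incomplete-T stops
before tRNAs; two rRNA-length AT-rich placeholders; 22 planted tRNAs of
47–63 nt with controlled topology (trnK cloverleaf, trnR armless, trnS1 and
half the rest D-armless, the others T-armless), controlled per-stem mismatch
loads and chosen anticodons; 70% AT spacers.  Spacer lengths default to
uniform 46–90 nt so every junction is searchable; around each run of
to-be-stripped tRNAs the flanking spacers share a budget so the merged gap
left after stripping stays inside the 46–215 nt window.  The whole genome
lands near 14–15 kb.

Spacers are rejection-sampled (bounded retries) against *strong decoys*: an
anchor for a stripped identity folding within caps at structure penalty ≤ 3,
i.e. a locus that could outcompete a genuine gene on structure alone.  A
blanket "no in-cap anchor anywhere" criterion is unattainable — with the
observed caps, random AT-rich sequence folds into the armless topology at
almost any anchor — which is exactly why the recovery score combines
conservation with structure.

Panels for synthetic runs are derived from the planted genes: homologs keep
the anticodon loop intact, tolerate at most one AC-stem substitution, and
diverge at 15% elsewhere — the conservation pattern that makes the
comparative method work on real mites.  The packaged
`data/panel_synthetic.tsv` is such a generated panel (a synthetic stand-in,
not real homologs; its filename says so).

What passing synthetic benchmarks shows: the machinery — windowed gap
extraction, anchored scanning including alternative anticodons, cap
filtering, conservation ranking, overlap resolution — recovers planted
degenerate genes and rejects excised ones under the stated conditions.  What
it does not show: performance on real genomes, where PCG sequence is not
random, rRNA boundaries are soft, panels are diverged real homologs, and
composition is skewed.

## Numerical and engineering choices

Coordinates are 0-based half-open internally, 1-based inclusive in reports;
origin-wrapping features keep `end > length` and normalize on access.  The
J-strand is defined operationally as the strand carrying the majority of
genes (ties: the strand of cox1).  All randomness flows through
`numpy.random.default_rng` seeds carried in the specs; identical inputs and
configuration give byte-identical reports.  The folding enumerator is
validated against an independently written exhaustive enumerator over all
geometries; both treat constraint ranges as inclusive.  rRNA boundaries are
taken from the input annotation as-is (deposited records pin them to their
neighbouring genes; this is checked, not assumed).

## Known limitations

- Recovery evidence is structural and comparative only; transcript data
  would be needed to confirm expression and editing.
- Boundary placement (especially the AA-stem) is ambiguous by nature; treat
  reported ends as ±2 nt.
- The gene-order reference arrangements are internally consistent but not
  guaranteed to match any particular deposited record gene-for-gene.
- The search is confined to inter-gene gaps; genes hidden inside annotated
  features (as one reanalysis proposed for trnE) are out of scope by design.
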