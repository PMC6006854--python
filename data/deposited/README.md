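# Deposited GenBank records (not redistributed)

The deposited-record checks in `tests/test_acceptance.py` read GenBank flat
files from this directory.  They are not bundled; fetch them from NCBI and
save them here under these exact names:

| file | accession | species |
|------|-----------|---------|
| `MF596167.gb` | MF596167 | *Histiostoma feroniarum* |
| `MF596168.gb` | MF596168 | *Rhizoglyphus robini* |
| `stmagnus.gb` | the *Steganacarus magnus* complete mitogenome | *St. magnus* |

For example:

```sh
curl -o MF596168.gb \
  'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=MF596168&rettype=gb&retmode=text'
```

The *St. magnus* recovery check additionally needs `panel.tsv` here: a
reference panel of real sarcoptiform mt tRNA homologs in the package's panel
TSV format (`identity`, `species`, `sequence`, `loop_start`, `loop_end`),
assembled from published annotations of species that retain the genes.
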