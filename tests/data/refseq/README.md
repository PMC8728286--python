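# RefSeq worked-example sequences (not distributed)

The worked-example mapping test (`tests/test_acceptance.py::
test_cited_refseq_position_mapping`) aligns three published ortholog pairs
and checks the corresponding-position mapping:

| human protein | model-organism ortholog | expected mapping |
|---|---|---|
| NP_001123996.1 (AP1M1)  | NP_001040675 (C. elegans UNC-101) | 375 ↔ 362 (P) |
| NP_000010 (ACAT1)       | NP_495455 (C. elegans KAT-1)      | 388 ↔ 368 (G) |
| NP_006079.1 (TUBB4B)    | NP_497728 (C. elegans BEN-1)      | 257 ↔ 257 (M) |

RefSeq sequences are not redistributed with this package; the test fails
with a pointer here until you download them. To populate this directory
(network required):

```sh
for acc in NP_001123996.1 NP_001040675 NP_000010 NP_495455 NP_006079.1 NP_497728; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=protein&id=${acc}&rettype=fasta&retmode=text" > "${acc}.fa"
done
```

Each file must be a single-record protein FASTA whose first header token
starts with the accession.
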