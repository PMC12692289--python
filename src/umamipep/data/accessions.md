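# Reference collagen accessions

The package does not fetch sequences from the network. To reproduce the
yak/bovine type I collagen analyses, download these public records as FASTA
and pass them to `umamipep identity` / `umamipep digest`:

| chain | organism | accession |
|---|---|---|
| collagen α1(I) | yak | ELR60286.1 |
| collagen α2(I) | yak | ELR46121.1 |
| collagen α1(I) | bovine | P02453.3 |
| collagen α2(I) | bovine | P02465.2 |

In their absence, `umamipep simulate` generates collagen-like Gly-X-Y
chains of comparable length and composition for testing every pipeline
stage.
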