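{
 "table1_species.tsv": "615dc5c969dbf79f22e8008e003fc95062d348db0d5cabbe819ca8bc6ff89b38",
 "table2_genes.tsv": "d05fa69b4c86fdf8236b7f3db0629ec8191621000fd3648f5b179284d779b934",
 "table3_primers.tsv": "46c9c12a0b18af2acd82d097457c969b9f7ccc3f6286b2a2632e9532b93eaa47"
}
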