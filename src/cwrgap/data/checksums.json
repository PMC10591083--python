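{
 "table1_genepool.tsv": "7a238affd024f88f5323296dba206838d90acb915fb30cdfd79ea9b57e046ef6",
 "table2_range_change.tsv": "d452faa19de4447ad071239eb853158a4db34a2aadf020f2ec388e95c5bec100"
}
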