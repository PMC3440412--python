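{
 "table1_sry_targets.tsv": "26a9adbec8051439e97820c0dc56407065fcc67668b1b9200a482a73c85a4f07",
 "table2_sox9_targets.tsv": "a08f1f164a7e168269287f56bc4fe29f34e7c9403663dfd06544dd09e76cd900"
}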