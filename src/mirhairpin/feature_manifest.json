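[
 "nt_proportion_A",
 "nt_proportion_C",
 "nt_proportion_G",
 "nt_proportion_U",
 "dinucleotide_proportion_AA",
 "dinucleotide_proportion_AC",
 "dinucleotide_proportion_AG",
 "dinucleotide_proportion_AU",
 "dinucleotide_proportion_CA",
 "dinucleotide_proportion_CC",
 "dinucleotide_proportion_CG",
 "dinucleotide_proportion_CU",
 "dinucleotide_proportion_GA",
 "dinucleotide_proportion_GC",
 "dinucleotide_proportion_GG",
 "dinucleotide_proportion_GU",
 "dinucleotide_proportion_UA",
 "dinucleotide_proportion_UC",
 "dinucleotide_proportion_UG",
 "dinucleotide_proportion_UU",
 "gc_content",
 "gc_ratio",
 "sequence_length",
 "stem_number",
 "avg_bp_stem",
 "longest_stem_length",
 "terminal_loop_length",
 "bp_number",
 "dP",
 "bp_proportion_AU",
 "bp_proportion_GC",
 "bp_proportion_GU",
 "bp_proportion_stem_AU",
 "bp_proportion_stem_GC",
 "bp_proportion_stem_GU",
 "triplets_0",
 "triplets_1",
 "triplets_2",
 "triplets_3",
 "triplets_4",
 "triplets_5",
 "triplets_6",
 "triplets_7",
 "triplets_8",
 "triplets_9",
 "triplets_10",
 "triplets_11",
 "triplets_12",
 "triplets_13",
 "triplets_14",
 "triplets_15",
 "triplets_16",
 "triplets_17",
 "triplets_18",
 "triplets_19",
 "triplets_20",
 "triplets_21",
 "triplets_22",
 "triplets_23",
 "triplets_24",
 "triplets_25",
 "triplets_26",
 "triplets_27",
 "triplets_28",
 "triplets_29",
 "triplets_30",
 "triplets_31",
 "MFE",
 "EFE",
 "ensemble_frequency",
 "diversity",
 "mfe_efe_difference",
 "dQ",
 "dG",
 "MFEI_1",
 "MFEI_2",
 "MFEI_4"
]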