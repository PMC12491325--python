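{
  "chain": "TRB",
  "v_segments": [
    ["TRBV1", "TGTGCCAGCAGTTTA", 0.09],
    ["TRBV2", "TGTGCCAGCAGC", 0.08],
    ["TRBV3", "TGCAGTGCTAGA", 0.07],
    ["TRBV4", "TGTGCCAGCAGTCCA", 0.07],
    ["TRBV5", "TGTGCCACCAGC", 0.06],
    ["TRBV6", "TGTGCCAGCTCA", 0.06],
    ["TRBV7", "TGTGCTTGGAGT", 0.06],
    ["TRBV8", "TGCAGTGCCAGA", 0.06],
    ["TRBV9", "TGTGCCAGCAGCGTA", 0.05],
    ["TRBV10", "TGTGCCATCAGC", 0.05],
    ["TRBV11", "TGTGCCAGCAGTGAA", 0.05],
    ["TRBV12", "TGTGCCAGTTCT", 0.05],
    ["TRBV13", "TGTGCCAGCAAG", 0.04],
    ["TRBV14", "TGTGCCTGGAGC", 0.04],
    ["TRBV15", "TGTGCCACCAGT", 0.04],
    ["TRBV16", "TGCAGTGCGAGG", 0.04],
    ["TRBV17", "TGTGCCAGCTCC", 0.03],
    ["TRBV18", "TGTGCCAGCATA", 0.03],
    ["TRBV19", "TGTGCCAGTACT", 0.02],
    ["TRBV20", "TGCAGCGCAAGA", 0.01]
  ],
  "d_segments": [
    ["TRBD1", "GGGACAGGGGGC", 0.55],
    ["TRBD2", "GGGACTAGCGGGGGG", 0.45]
  ],
  "j_segments": [
    ["TRBJ1-1", "AACACTGAAGCTTTCTTT", 0.12],
    ["TRBJ1-2", "AACTATGGCTACACCTTC", 0.10],
    ["TRBJ1-3", "TCTGGAAACACCATATATTTT", 0.06],
    ["TRBJ1-4", "ACTAATGAAAAACTGTTTTTT", 0.06],
    ["TRBJ1-5", "AGCAATCAGCCCCAGCATTTT", 0.08],
    ["TRBJ1-6", "TCCTATAATTCACCCCTCCACTTT", 0.05],
    ["TRBJ2-1", "AATGAGCAGTTCTTC", 0.14],
    ["TRBJ2-2", "AACACCGGGGAGCTGTTTTTT", 0.06],
    ["TRBJ2-3", "AGCACAGATACGCAGTATTTT", 0.09],
    ["TRBJ2-4", "GCCAAAAACATTCAGTACTTC", 0.04],
    ["TRBJ2-5", "CAAGAGACCCAGTACTTC", 0.10],
    ["TRBJ2-7", "TCCTACGAGCAGTACTTC", 0.10]
  ],
  "trim_p": {"v3": 0.45, "d5": 0.35, "d3": 0.35, "j5": 0.35},
  "insert_p": 0.28,
  "insert_base_probs": {"A": 0.18, "C": 0.28, "G": 0.34, "T": 0.20}
}
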