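{
  "chain": "TRA",
  "v_segments": [
    ["TRAV1", "TGTGCTGTG", 0.09],
    ["TRAV2", "TGTGCTGCC", 0.08],
    ["TRAV3", "TGTGCAATG", 0.07],
    ["TRAV4", "TGTCTCGTG", 0.07],
    ["TRAV5", "TGTGCAGAG", 0.07],
    ["TRAV6", "TGTGCTCTA", 0.06],
    ["TRAV7", "TGTGCTGTGAGA", 0.06],
    ["TRAV8", "TGTGCCGTG", 0.06],
    ["TRAV9", "TGTGCTTTG", 0.06],
    ["TRAV10", "TGTGTGGTG", 0.05],
    ["TRAV12", "TGTGTTGTC", 0.05],
    ["TRAV13", "TGTGCAGCA", 0.05],
    ["TRAV14", "TGTGCAATGAGA", 0.05],
    ["TRAV16", "TGTGCTCTG", 0.04],
    ["TRAV17", "TGTGCTACG", 0.04],
    ["TRAV19", "TGTGCTCTGAGT", 0.04],
    ["TRAV21", "TGTGCTGTT", 0.03],
    ["TRAV24", "TGTGCCTTC", 0.01],
    ["TRAV26", "TGCATCGTC", 0.01],
    ["TRAV27", "TGTGCAGGA", 0.01]
  ],
  "d_segments": [],
  "j_segments": [
    ["TRAJ37", "GGCTCTAGCAACACAGGCAAACTAATCTTT", 0.10],
    ["TRAJ42", "AATTATGGAGGAAGCCAAGGAAATCTCATCTTT", 0.09],
    ["TRAJ49", "AACACCGGTAACCAGTATTTC", 0.05],
    ["TRAJ45", "TATTCAGGAGGAGGTGCTGACGGACTCACCTTT", 0.10],
    ["TRAJ33", "GATAGCAACTATCAGTTAATCTGG", 0.11],
    ["TRAJ20", "AACGACTACAAGCTCAGCTTT", 0.10],
    ["TRAJ27", "AATACAAATGCAGGCAAATCAACCTTT", 0.10],
    ["TRAJ12", "ATGGATAGCAGCTATAAATTGATCTTC", 0.10],
    ["TRAJ53", "AATAGTGGAGGTAGCAACTATAAACTGACATTT", 0.10],
    ["TRAJ31", "AATAATAATGCCAGACTCATGTTT", 0.10],
    ["TRAJ40", "ACCTACAAATACATCTTT", 0.03],
    ["TRAJ22", "TCTTCTGGTTCTGCAAGGCAACTGACCTTT", 0.02]
  ],
  "trim_p": {"v3": 0.45, "d5": 0.35, "d3": 0.35, "j5": 0.30},
  "insert_p": 0.25,
  "insert_base_probs": {"A": 0.22, "C": 0.26, "G": 0.30, "T": 0.22}
}
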