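{
  "pairs": [
    {
      "gene_a": "ABCA1",
      "gene_b": "PYGL",
      "coefficient": 0.2196
    },
    {
      "gene_a": "HMOX1",
      "gene_b": "NAGLU",
      "coefficient": 0.182
    },
    {
      "gene_a": "GALNT10",
      "gene_b": "PIM1",
      "coefficient": 0.157
    },
    {
      "gene_a": "JAK3",
      "gene_b": "SMPD1",
      "coefficient": -0.143
    },
    {
      "gene_a": "PDGFC",
      "gene_b": "PTPRE",
      "coefficient": 0.128
    },
    {
      "gene_a": "PLOD2",
      "gene_b": "TK1",
      "coefficient": -0.117
    },
    {
      "gene_a": "MTHFD2",
      "gene_b": "SLC44A1",
      "coefficient": 0.0248
    },
    {
      "gene_a": "AMT",
      "gene_b": "HK2",
      "coefficient": 0.104
    },
    {
      "gene_a": "BDH2",
      "gene_b": "ELOVL2",
      "coefficient": -0.096
    },
    {
      "gene_a": "FSTL3",
      "gene_b": "PLCB1",
      "coefficient": 0.089
    },
    {
      "gene_a": "HSPA2",
      "gene_b": "UGCG",
      "coefficient": -0.081
    },
    {
      "gene_a": "PLA2G4C",
      "gene_b": "ST6GAL1",
      "coefficient": 0.074
    },
    {
      "gene_a": "NUDT11",
      "gene_b": "P4HA2",
      "coefficient": 0.068
    },
    {
      "gene_a": "ACSL3",
      "gene_b": "PIM1",
      "coefficient": -0.061
    },
    {
      "gene_a": "ALDH3B1",
      "gene_b": "SLC44A1",
      "coefficient": 0.048
    },
    {
      "gene_a": "B3GNT2",
      "gene_b": "PTPRE",
      "coefficient": -0.033
    },
    {
      "gene_a": "BDH2",
      "gene_b": "CHST2",
      "coefficient": 0.029
    },
    {
      "gene_a": "CYP2J2",
      "gene_b": "GPCPD1",
      "coefficient": -0.021
    },
    {
      "gene_a": "DGKA",
      "gene_b": "ITPKB",
      "coefficient": 0.018
    },
    {
      "gene_a": "IDO1",
      "gene_b": "MBOAT2",
      "coefficient": -0.012
    },
    {
      "gene_a": "GXYLT2",
      "gene_b": "PFKFB3",
      "coefficient": 0.008
    }
  ],
  "cutoff": -0.211,
  "horizon_months": 12.0,
  "tie_rule": "gt_zero_ties",
  "metadata": {
    "synthetic": true,
    "description": "Synthetic stand-in for a published 21-pair metabolic gene-pair glioblastoma signature whose full supplementary table is not redistributable: pair list and most coefficients are constructed, matching only the published structural facts (21 pairs, 38 unique genes, 13 entries with |coefficient| > 0.05, risk cutoff -0.211, strongest coefficient 0.2196 on an ABCA1 pair, 0.0248 on an MTHFD2 pair). Not for biological interpretation."
  }
}
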