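{
  "chrom": "chr17",
  "comment": "TP53 locus, GRCh38, minus strand. Exons listed 5'->3' in transcript order (descending genomic coordinates). Coordinates mirror the public reference annotation for the listed accessions; swap this file to use another annotation release.",
  "transcripts": [
    {
      "id": "NM_000546.6",
      "strand": "-",
      "role": "main",
      "exons": [
        [7687377, 7687490],
        [7676521, 7676622],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001126114.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "cterm",
      "exons": [
        [7687377, 7687490],
        [7676521, 7676622],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7672574, 7672710],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001276696.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "cterm",
      "exons": [
        [7687377, 7687490],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7672574, 7672710],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001126116.1",
      "strand": "-",
      "role": "alternative",
      "junction_role": "cterm",
      "exons": [
        [7675760, 7675920],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7672574, 7672710],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001276698.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "cterm",
      "exons": [
        [7675780, 7675940],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7672574, 7672710],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001126113.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "gamma",
      "exons": [
        [7687377, 7687490],
        [7676521, 7676622],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7671700, 7671801],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001276695.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "gamma",
      "exons": [
        [7687377, 7687490],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7671700, 7671801],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001126117.1",
      "strand": "-",
      "role": "alternative",
      "junction_role": "gamma",
      "exons": [
        [7675760, 7675920],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7671700, 7671801],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001276699.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "gamma",
      "exons": [
        [7675780, 7675940],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7671700, 7671801],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    },
    {
      "id": "NM_001126112.2",
      "strand": "-",
      "role": "alternative",
      "junction_role": "utr5",
      "exons": [
        [7687377, 7687490],
        [7676521, 7676619],
        [7676382, 7676403],
        [7675994, 7676272],
        [7675053, 7675236],
        [7674859, 7674971],
        [7674181, 7674290],
        [7673701, 7673837],
        [7673535, 7673608],
        [7670609, 7670715],
        [7668402, 7669690]
      ]
    }
  ]
}
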