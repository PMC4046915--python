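name: ecoli_ccm
mu: 2.78e-05
metabolites:
- g6p
- f6p
- fdp
- gap
- dhap
- pgp
- pg3
- pg2
- pep
- pyr
- 6pg
- ribu5p
- xyl5p
- sed7p
- rib5p
- e4p
- g1p
- glcex
cometabolites:
  atp: 4.27
  adp: 0.595
  amp: 0.955
  nad: 1.47
  nadh: 0.1
  nadp: 0.195
  nadph: 0.062
  glcex: 0.0556
reactions:
- id: PTS
  kind: pts
  metabolites:
  - pep
  - pyr
  - g6p
  - glcex
  params:
    rmax: 508781.83996287483
    Ka1: 3082.3
    Ka2: 0.01
    Ka3: 245.3
    Kg6p: 2.15
    ng6p: 3.66
- id: PGI
  kind: pgi
  metabolites:
  - g6p
  - f6p
  - 6pg
  params:
    rmax: 650.988
    Keq: 0.1725
    Kg6p: 2.9
    Kf6p: 0.266
    Kf6p_6pg: 0.2
    Kg6p_6pg: 0.2
- id: PGM
  kind: rev_uni_mm
  metabolites:
  - g6p
  - g1p
  params:
    rmax: 0.839824
    Keq: 0.196
    Ka: 1.038
    Kb: 0.0136
- id: G6PDH
  kind: g6pdh
  metabolites:
  - g6p
  params:
    rmax: 1.3802
    Kg6p: 14.4
    Knadp: 0.0246
    Knadph_g6p: 6.43
    Knadph_nadp: 0.01
- id: PFK
  kind: pfk
  metabolites:
  - f6p
  - pep
  params:
    rmax: 1932.609
    Katp: 0.123
    Kadp_c: 4.14
    Kf6p: 0.325
    Kpep: 3.26
    Kadp_b: 3.89
    Kamp_b: 3.2
    Kadp_a: 128.0
    Kamp_a: 19.1
    L: 5629070.0
    n: 11.1
- id: TA
  kind: rev_bi_ma
  metabolites:
  - gap
  - sed7p
  - e4p
  - f6p
  params:
    rmax: 10.8716
    Keq: 1.05
- id: TKA
  kind: rev_bi_ma
  metabolites:
  - rib5p
  - xyl5p
  - sed7p
  - gap
  params:
    rmax: 9.47338
    Keq: 1.2
- id: TKB
  kind: rev_bi_ma
  metabolites:
  - xyl5p
  - e4p
  - f6p
  - gap
  params:
    rmax: 86.5586
    Keq: 10.0
- id: MURSYNTH
  kind: constant
  metabolites: []
  params:
    rmax: 0.00043711
- id: ALDO
  kind: aldo
  metabolites:
  - fdp
  - gap
  - dhap
  params:
    rmax: 17.4146
    Keq: 0.144
    Kfdp: 1.75
    Kgap: 0.088
    Kdhap: 0.088
    blf: 2.0
    Kgap_inh: 0.6
- id: GAPDH
  kind: gapdh
  metabolites:
  - gap
  - pgp
  params:
    rmax: 921.594
    Keq: 0.63
    Kgap: 0.683
    Kpgp: 1.04e-05
    Knad: 0.252
    Knadh: 1.09
- id: TIS
  kind: rev_uni_mm
  metabolites:
  - dhap
  - gap
  params:
    rmax: 68.6747
    Keq: 1.39
    Ka: 2.8
    Kb: 0.3
- id: G3PDH
  kind: mm1
  metabolites:
  - dhap
  params:
    rmax: 0.0116204
    Km: 1.0
- id: PGK
  kind: pgk
  metabolites:
  - pgp
  - pg3
  params:
    rmax: 3021.77
    Keq: 1934.4
    Kadp: 0.185
    Katp: 0.653
    Kpgp: 0.0468
    Kpg3: 0.473
- id: SER
  kind: mm1
  metabolites:
  - pg3
  params:
    rmax: 0.025712
    Km: 1.0
- id: PGLUMU
  kind: rev_uni_mm
  metabolites:
  - pg3
  - pg2
  params:
    rmax: 89.0497
    Keq: 0.188
    Ka: 0.2
    Kb: 0.369
- id: ENO
  kind: rev_uni_mm
  metabolites:
  - pg2
  - pep
  params:
    rmax: 330.448
    Keq: 6.73
    Ka: 0.1
    Kb: 0.135
- id: PK
  kind: pk
  metabolites:
  - pep
  - fdp
  params:
    rmax: 0.064188075
    Kpep: 0.31
    n: 4.0
    L: 1000.0
    Katp: 22.5
    Kfdp: 0.19
    Kamp: 0.2
    Kadp: 0.26
- id: PEPC
  kind: pepc
  metabolites:
  - pep
  - fdp
  params:
    rmax: 0.107021
    Kpep: 4.07
    Kfdp: 0.7
    nfdp: 4.21
- id: SYN1
  kind: mm1
  metabolites:
  - pep
  params:
    rmax: 0.019539
    Km: 1.0
- id: SYN2
  kind: mm1
  metabolites:
  - pyr
  params:
    rmax: 0.0736186
    Km: 1.0
- id: DAHPS
  kind: dahps
  metabolites:
  - e4p
  - pep
  params:
    rmax: 0.107953
    Ke4p: 0.035
    ne4p: 2.6
    Kpep: 0.0053
    npep: 2.2
- id: PDH
  kind: hill1
  metabolites:
  - pyr
  params:
    rmax: 6.05953
    K: 1159.0
    n: 3.68
- id: METSYNTH
  kind: constant
  metabolites: []
  params:
    rmax: 0.0022627
- id: PGDH
  kind: pgdh
  metabolites:
  - 6pg
  params:
    rmax: 16.2324
    K6pg: 37.5
    Knadp: 0.0506
    Knadph: 0.0138
    Katp: 208.0
- id: R5PI
  kind: rev_uni_ma
  metabolites:
  - ribu5p
  - rib5p
  params:
    rmax: 4.83841
    Keq: 4.0
- id: RU5P
  kind: rev_uni_ma
  metabolites:
  - ribu5p
  - xyl5p
  params:
    rmax: 6.73903
    Keq: 1.4
- id: RPPK
  kind: mm1
  metabolites:
  - rib5p
  params:
    rmax: 0.0129005
    Km: 0.1
- id: G1PAT
  kind: g1pat
  metabolites:
  - g1p
  - fdp
  params:
    rmax: 0.00752546
    Kg1p: 3.2
    Katp: 4.42
    Kfdp: 0.119
    nfdp: 1.2
- id: TRPSYNTH
  kind: constant
  metabolites: []
  params:
    rmax: 0.001037
- id: PPS
  kind: pps
  metabolites:
  - pyr
  - pep
  params:
    rmax: 0.002043973701898816
    Kpyr: 0.083
    Kipep: 2.0
- id: FBP
  kind: fbp
  metabolites:
  - fdp
  params:
    rmax: 0.04569043394228428
    Kfdp: 0.02
    Kiamp: 0.19
stoichiometry:
- - g6p
  - PTS
  - 1.0
- - g6p
  - PGI
  - -1.0
- - g6p
  - PGM
  - -1.0
- - g6p
  - G6PDH
  - -1.0
- - f6p
  - PGI
  - 1.0
- - f6p
  - PFK
  - -1.0
- - f6p
  - TA
  - 1.0
- - f6p
  - TKB
  - 1.0
- - f6p
  - MURSYNTH
  - -2.0
- - f6p
  - FBP
  - 1.0
- - fdp
  - PFK
  - 1.0
- - fdp
  - ALDO
  - -1.0
- - fdp
  - FBP
  - -1.0
- - gap
  - TA
  - -1.0
- - gap
  - TKA
  - 1.0
- - gap
  - TKB
  - 1.0
- - gap
  - ALDO
  - 1.0
- - gap
  - GAPDH
  - -1.0
- - gap
  - TIS
  - 1.0
- - gap
  - TRPSYNTH
  - 1.0
- - dhap
  - ALDO
  - 1.0
- - dhap
  - TIS
  - -1.0
- - dhap
  - G3PDH
  - -1.0
- - pgp
  - GAPDH
  - 1.0
- - pgp
  - PGK
  - -1.0
- - pg3
  - PGK
  - 1.0
- - pg3
  - SER
  - -1.0
- - pg3
  - PGLUMU
  - -1.0
- - pg2
  - PGLUMU
  - 1.0
- - pg2
  - ENO
  - -1.0
- - pep
  - PTS
  - -1.0
- - pep
  - ENO
  - 1.0
- - pep
  - PK
  - -1.0
- - pep
  - PEPC
  - -1.0
- - pep
  - SYN1
  - -1.0
- - pep
  - DAHPS
  - -1.0
- - pep
  - PPS
  - 1.0
- - pyr
  - PTS
  - 1.0
- - pyr
  - PK
  - 1.0
- - pyr
  - SYN2
  - -1.0
- - pyr
  - PDH
  - -1.0
- - pyr
  - METSYNTH
  - 1.0
- - pyr
  - PPS
  - -1.0
- - 6pg
  - G6PDH
  - 1.0
- - 6pg
  - PGDH
  - -1.0
- - ribu5p
  - PGDH
  - 1.0
- - ribu5p
  - R5PI
  - -1.0
- - ribu5p
  - RU5P
  - -1.0
- - xyl5p
  - TKA
  - -1.0
- - xyl5p
  - TKB
  - -1.0
- - xyl5p
  - RU5P
  - 1.0
- - sed7p
  - TA
  - -1.0
- - sed7p
  - TKA
  - 1.0
- - rib5p
  - TKA
  - -1.0
- - rib5p
  - R5PI
  - 1.0
- - rib5p
  - RPPK
  - -1.0
- - e4p
  - TA
  - 1.0
- - e4p
  - TKB
  - -1.0
- - e4p
  - DAHPS
  - -1.0
- - g1p
  - PGM
  - 1.0
- - g1p
  - G1PAT
  - -1.0
- - glcex
  - PTS
  - -0.015401086978072973
steady_state:
  g6p: 3.4792550685570696
  f6p: 0.5998717165994893
  fdp: 0.27161894139330234
  gap: 0.217840725116149
  dhap: 0.16687889894471827
  pgp: 0.007996432069954191
  pg3: 2.1300547905409024
  pg2: 0.3988234464915074
  pep: 2.6688227766276826
  pyr: 2.665708707002723
  6pg: 0.8073575626308483
  ribu5p: 0.11096347827689591
  xyl5p: 0.13795141019075977
  sed7p: 0.275997747675964
  rib5p: 0.39786340358318495
  e4p: 0.0979448677803876
  g1p: 0.6523984133965974
  glcex: 0.05549215907215279
essential:
- RPPK
- GAPDH
- PGK
- ENO
- PTS
inflow:
  glcex: 0.003084688
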