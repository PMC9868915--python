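# Central carbon metabolism of heterotrophic arabidopsis cell suspensions:
# cytosolic and plastidic glycolysis, oxidative and non-oxidative pentose
# phosphate pathway, TCA cycle with anaplerotic PEP carboxylase and malic
# enzyme, sucrose/starch/cell-wall synthesis and biomass outputs.  Atom maps
# are textbook central-metabolism maps (aldolase C1-C3/C4-C6 split with DHAP
# inversion, transketolase C1-C2 and transaldolase C1-C3 units, citrate
# synthase acetyl + oxaloacetate condensation with both CO2 losses of one
# TCA turn drawn from oxaloacetate carbons, succinate/fumarate scrambling).
# Compartment suffixes: .c cytosol, .p plastid, .m mitochondrion, .v vacuole.

pool GLC.ext 6 source
pool GLC.v 6 source unlabelled
pool GLC.int 6
pool G6P.c 6
pool F6P.c 6
pool FBP.c 6
pool TP.c 3
pool 3PG.c 3
pool PEP.c 3
pool PYR.c 3
pool G1P.c 6
pool UDPG 6
pool 6PG.c 6
pool R5P.c 5
pool G6P.p 6
pool F6P.p 6
pool FBP.p 6
pool TP.p 3
pool 3PG.p 3
pool PEP.p 3
pool PYR.p 3
pool G1P.p 6
pool 6PG.p 6
pool R5P.p 5
pool X5P.p 5
pool S7P.p 7
pool E4P.p 4
pool TKC2.p 2
pool TAC3.p 3
pool PYR.m 3
pool AcCoA 2
pool CIT 6
pool ICIT 6
pool 2OG 5
pool SUCCoA 4
pool SUCC 4 symmetric
pool FUM 4 symmetric
pool MAL 4
pool CO2 1
pool CO2.eff 1 sink
pool S6P.out 12 sink
pool CWALL.out 6 sink
pool STARCH.out 6 sink
pool R5P.out 5 sink
pool ALA.out 3 sink
pool LIP.out 3 sink
pool GLU.out 5 sink
pool ASP.out 4 sink
pool ACL.out 2 sink

# -- uptake and dilution by pre-existing unlabelled glucose
rxn glcx: GLC.ext (abcdef) -> GLC.int (abcdef) class=transport
rxn Glcv: GLC.v (abcdef) -> GLC.int (abcdef) class=transport
rxn upt: GLC.int (abcdef) -> G6P.c (abcdef) class=hexose

# -- cytosolic glycolysis
rxn chex1: G6P.c (abcdef) <-> F6P.c (abcdef) class=hexose
rxn chex2a: F6P.c (abcdef) <-> FBP.c (abcdef) class=hexose
rxn chex2: FBP.c (abcdef) <-> TP.c (cba) + TP.c (def) class=hexose
rxn chex3-1: TP.c (abc) <-> 3PG.c (abc) class=hexose
rxn chex3-2: 3PG.c (abc) <-> PEP.c (abc) class=hexose
rxn chex3: PEP.c (abc) -> PYR.c (abc) class=hexose

# -- sucrose and cell-wall synthesis
rxn chex4/5: G6P.c (abcdef) <-> G1P.c (abcdef) class=synthesis
rxn ugp: G1P.c (abcdef) <-> UDPG (abcdef) class=synthesis
rxn cwall: G1P.c (abcdef) -> CWALL.out (abcdef) class=output
rxn chex6: F6P.c (abcdef) + UDPG (ghijkl) -> S6P.out (ghijklabcdef) class=synthesis

# -- cytosolic oxidative PPP
rxn cppp1: G6P.c (abcdef) -> 6PG.c (abcdef) class=PPP
rxn cppp2: 6PG.c (abcdef) -> CO2 (a) + R5P.c (bcdef) class=PPP
rxn nucc: R5P.c (abcde) -> R5P.out (abcde) class=output

# -- transporters
rxn gpt: G6P.c (abcdef) <-> G6P.p (abcdef) class=transport
rxn tpt: TP.c (abc) <-> TP.p (abc) class=transport
rxn cmex: PYR.c (abc) -> PYR.m (abc) class=transport
rxn cpex: PYR.c (abc) -> PYR.p (abc) class=transport

# -- plastidic glycolysis and starch synthesis
rxn phex1: G6P.p (abcdef) <-> F6P.p (abcdef) class=hexose
rxn phex2a: F6P.p (abcdef) <-> FBP.p (abcdef) class=hexose
rxn phex2: FBP.p (abcdef) <-> TP.p (cba) + TP.p (def) class=hexose
rxn phex3-1: TP.p (abc) <-> 3PG.p (abc) class=hexose
rxn phex3-2: 3PG.p (abc) <-> PEP.p (abc) class=hexose
rxn phex3: PEP.p (abc) -> PYR.p (abc) class=hexose
rxn phex4/5: G6P.p (abcdef) <-> G1P.p (abcdef) class=synthesis
rxn starch: G1P.p (abcdef) -> STARCH.out (abcdef) class=output

# -- plastidic pentose phosphate pathway
rxn pppp1: G6P.p (abcdef) -> 6PG.p (abcdef) class=PPP
rxn pppp1b: 6PG.p (abcdef) -> CO2 (a) + R5P.p (bcdef) class=PPP
rxn rpe: R5P.p (abcde) <-> X5P.p (abcde) class=PPP
rxn pppp2c: X5P.p (abcde) <-> TP.p (cde) + TKC2.p (ab) class=PPP
rxn pppp2a: R5P.p (abcde) + TKC2.p (fg) <-> S7P.p (fgabcde) class=PPP
rxn pppp3a: S7P.p (abcdefg) <-> TAC3.p (abc) + E4P.p (defg) class=PPP
rxn pppp3b: TP.p (abc) + TAC3.p (def) <-> F6P.p (defabc) class=PPP
rxn pppp2b: E4P.p (abcd) + TKC2.p (ef) <-> F6P.p (efabcd) class=PPP
rxn nucp: R5P.p (abcde) -> R5P.out (abcde) class=output
rxn plip: PYR.p (abc) -> LIP.out (abc) class=output

# -- TCA cycle
rxn tca1: PYR.m (abc) -> CO2 (a) + AcCoA (bc) class=tca
rxn tca2: AcCoA (ab) + MAL (cdef) -> CIT (abfedc) class=tca
rxn aco: CIT (abcdef) <-> ICIT (abcdef) class=tca
rxn tca3: ICIT (abcdef) -> CO2 (f) + 2OG (abcde) class=tca
rxn tca4: 2OG (abcde) -> CO2 (e) + SUCCoA (abcd) class=tca
rxn tca4b: SUCCoA (abcd) -> SUCC (abcd) class=tca
rxn tca5: SUCC (abcd) <-> FUM (abcd) class=tca
rxn tca6: FUM (abcd) <-> MAL (abcd) class=tca

# -- anaplerotic fluxes
rxn ana1: PEP.c (abc) + CO2 (d) <-> MAL (abcd) class=anaplerotic
rxn ana2: MAL (abcd) -> PYR.m (abc) + CO2 (d) class=anaplerotic
rxn ana3: MAL (abcd) -> PYR.p (abc) + CO2 (d) class=anaplerotic

# -- biomass outputs and CO2 efflux
rxn alaout: PYR.c (abc) -> ALA.out (abc) class=output
rxn gluout: 2OG (abcde) -> GLU.out (abcde) class=output
rxn aspout: MAL (abcd) -> ASP.out (abcd) class=output
rxn aclout: AcCoA (ab) -> ACL.out (ab) class=output
rxn CO2out: CO2 (a) -> CO2.eff (a) class=output

fix upt 1.0
substrate GLC.ext 0.4 0 0 0 0 0 0.6

measure G6P: G6P.c + G6P.p
measure F6P: F6P.c + F6P.p
measure TP: TP.c + TP.p
measure 3PG: 3PG.c + 3PG.p
measure PEP: PEP.c + PEP.p
measure PYR: PYR.c + PYR.p + PYR.m
measure G1P: G1P.c + G1P.p
measure UDPG: UDPG
measure 6PG: 6PG.c + 6PG.p
measure CIT: CIT unlabelled
measure ICIT: ICIT unlabelled
measure 2OG: 2OG
measure SUCC: SUCC unlabelled
measure FUM: FUM unlabelled
measure MAL: MAL unlabelled
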