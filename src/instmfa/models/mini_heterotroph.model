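# Desk-scale heterotrophic central-metabolism network with carbon skeletons
# lumped to 1-3 atoms.  It keeps the flux motif that drives the full network:
# glucose uptake (fixed at 1, the flux normalization), dilution by
# pre-existing unlabelled stores, a pyruvate-kinase branch competing with the
# PEP-carboxylase / malic-enzyme anaplerotic pair, decarboxylation feeding a
# balanced CO2 pool that is refixed by carboxylation, and a slow organic-acid
# pool observed with vacuolar (metabolically inactive) dilution.
pool GLC.ext 2 source
pool GLC.v 2 source unlabelled
pool PEP.c 2
pool PYR.c 2
pool MAL.c 3
pool CO2 1
pool ACA.out 1 sink
pool PYR.out 2 sink
pool MAL.out 3 sink
pool CO2.eff 1 sink

rxn upt: GLC.ext (ab) -> PEP.c (ab) class=hexose
rxn glcv: GLC.v (ab) -> PEP.c (ab) class=hexose
rxn pk: PEP.c (ab) -> PYR.c (ab) class=hexose
rxn ana1: PEP.c (ab) + CO2 (c) <-> MAL.c (abc) class=anaplerotic
rxn ana2: MAL.c (abc) -> PYR.c (ab) + CO2 (c) class=anaplerotic
rxn pdh: PYR.c (ab) -> CO2 (a) + ACA.out (b) class=tca
rxn pyrout: PYR.c (ab) -> PYR.out (ab) class=output
rxn malout: MAL.c (abc) -> MAL.out (abc) class=output
rxn co2out: CO2 (a) -> CO2.eff (a) class=output

fix upt 1.0
substrate GLC.ext 0.4 0 0.6

measure PEP: PEP.c
measure PYR: PYR.c
measure MAL: MAL.c unlabelled
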