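family,species,pollard_sites,malaise_sites,inat_observations
Hesperiidae,Erynnis funeralis,9,6,4
Hesperiidae,Heliopetes ericetorum,1,2,0
Hesperiidae,Hylephila phyleus,13,9,17
Hesperiidae,Lerodea eufala,10,9,4
Hesperiidae,Ochlodes sylvanoides,1,0,0
Hesperiidae,Poanes melane,4,14,4
Hesperiidae,Pyrgus albescens,1,0,0
Papilionidae,Papilio eurymedon,1,0,0
Papilionidae,Papilio rumiko,3,1,2
Papilionidae,Papilio rutulus,10,0,4
Papilionidae,Papilio zelicaon,7,1,1
Pieridae,Colias eurytheme,8,0,0
Pieridae,Nathalis iole,1,0,0
Pieridae,Phoebis sennae,14,2,3
Pieridae,Pieris rapae,16,14,4
Pieridae,Pontia protodice,1,2,1
Nymphalidae,Adelpha californica,0,0,4
Nymphalidae,Agraulis vanillae,15,6,9
Nymphalidae,Danaus gilippus,1,0,0
Nymphalidae,Danaus plexippus,15,4,15
Nymphalidae,Junonia coenia,1,0,2
Nymphalidae,Limenitis lorquini,0,0,1
Nymphalidae,Nymphalis antiopa,5,0,4
Nymphalidae,Vanessa annabella,4,2,2
Nymphalidae,Vanessa atalanta,8,3,7
Nymphalidae,Vanessa cardui,13,3,3
Lycaenidae,Brephidium exilis,0,1,2
Lycaenidae,Icaricia acmon,3,0,0
Lycaenidae,Leptotes marina,9,10,8
Lycaenidae,Strymon melinus,7,6,3
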