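,premaxilla,maxilla,nasal,lacrimal,prefrontal,frontal,postorbital,jugal,squamosal,quadratojugal,quadrate,parietal,preparietal,postparietal,vomer,palatine,ectopterygoid,pterygoid,epipterygoid,parasphenoid,basisphenoid,prootic,opisthotic,supraoccipital,exoccipital,basioccipital,stapes
premaxilla,0,1,1,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
maxilla,1,0,1,1,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
nasal,1,1,0,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
lacrimal,0,1,1,0,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
prefrontal,0,0,1,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
frontal,0,0,1,0,1,0,1,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
postorbital,0,0,0,0,0,1,0,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
jugal,0,1,0,1,0,0,1,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
squamosal,0,0,0,0,0,0,1,1,0,1,1,1,0,0,0,0,0,0,0,0,0,0,?,0,0,0,0
quadratojugal,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
quadrate,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,1
parietal,0,0,0,0,0,1,1,0,1,0,0,0,1,1,0,0,0,0,0,0,0,0,0,?,0,0,0
preparietal,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
postparietal,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0
vomer,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,0,?,0,0,0,0,0,0,0
palatine,0,1,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,1,0,0,0,0,0,0,0,0,0
ectopterygoid,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0
pterygoid,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1,1,1,0,1,0,1,0,0,0,0,0,0
epipterygoid,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,1,1,0,0,0,0,0
parasphenoid,0,0,0,0,0,0,0,0,0,0,0,0,0,0,?,0,0,0,0,0,1,0,0,0,0,0,0
basisphenoid,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,0,1,0,0,0,1,0
prootic,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,0,1,1,0,0,?
opisthotic,0,0,0,0,0,0,0,0,?,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,1,1,?
supraoccipital,0,0,0,0,0,0,0,0,0,0,0,?,0,1,0,0,0,0,0,0,0,1,1,0,1,0,0
exoccipital,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,1,0
basioccipital,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,0,1,0,0
stapes,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,?,?,0,0,0,0
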