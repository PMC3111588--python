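# Synthetic stand-in drug-name list.
advil
arimidex
aspirin
celebrex
doxycycline
enbrel
herceptin
humira
ibuprofen
methotrexate
naproxen
nurofen
plaquenil
prednisone
remicade
tamoxifen
taxol
tylenol
zoladex
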