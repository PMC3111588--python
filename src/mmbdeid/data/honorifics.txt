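# Honorific titles, compiled by hand.
dr
madam
miss
mr
mrs
ms
prof
rev
sir
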