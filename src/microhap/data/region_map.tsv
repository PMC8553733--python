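# source: mapping of roster world regions to the 6 biogeographic regions (K=6 clusters)
# lines starting with '@' override the region of a single population (abbrev)
key	region
Central Africa	Africa, Sub-Sahara
West Africa	Africa, Sub-Sahara
East Africa	Africa, Sub-Sahara
North Africa	N Africa, SW Asia, Europe
Southwest Asia	N Africa, SW Asia, Europe
Europe	N Africa, SW Asia, Europe
So Central Asia	South Central Asia
East Asia	East Asia
Oceania	Oceania
Americas	Americas
@MOG	South Central Asia
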