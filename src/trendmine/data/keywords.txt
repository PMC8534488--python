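vaccine
vaccines
#vaccine
#vaccines
corona vaccine
corona vaccines
#coronavaccine
#coronavaccines
pfizer
biontech
moderna
pfizer-biontech
pfizer/biontech
pfizer biontech
#pfizerbiontech
covax
sinopharm
sinovac
astrazeneca
sputnik v
gamaleya
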