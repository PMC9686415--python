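# Curated literature list of muscle structure / development genes
# (myogenesis, collagen synthesis, oxidative response, immune response)
myod
myog
hsp90
smad3
smad4
gsk3b
wnt8a
wnt11
axin2
stat1
stat2
jak2
tgf-b1
col1a1
col1a2
col1a3
col4a1
col18a1
g6pdh
gst
gss
cat
prdx6
pex7
nfkb1
tnf-a
ifn-g
il-4
il-10
il-12
il-21
il-23
mhc-i
mhc-ii
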