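not
no
never
none
nothing
neither
nobody
nor
isnt
arent
wasnt
werent
dont
doesnt
didnt
cant
couldnt
wont
wouldnt
shouldnt
aint
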