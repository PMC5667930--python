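luv	love
gr8	great
u	you
ur	your
thx	thanks
pls	please
rly	really
gud	good
gd	good
amazin	amazing
b4	before
2nite	tonight
tho	though
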