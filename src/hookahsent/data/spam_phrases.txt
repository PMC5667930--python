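click here
free followers
follow back guaranteed
hot singles
limited offer
win big now
dm for promo
check my bio
instant followers
make money fast
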