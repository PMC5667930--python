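excited	0.8
thrilled	0.85
active	0.7
alert	0.6
party	0.6
stoked	0.7
energetic	0.7
amazing	0.5
awesome	0.5
fantastic	0.5
angry	0.7
mad	0.7
stressed	0.6
tense	0.55
nervous	0.6
scared	0.65
afraid	0.6
upset	0.5
annoying	0.45
hate	0.5
love	0.4
happy	0.35
fun	0.4
wonderful	0.3
great	0.3
disgusting	0.4
gross	0.35
nasty	0.35
foul	0.35
calm	-0.7
relaxed	-0.65
relaxing	-0.6
serene	-0.7
chill	-0.6
cozy	-0.5
sleepy	-0.8
tired	-0.6
bored	-0.5
boring	-0.5
sad	-0.4
unhappy	-0.35
depressed	-0.5
miserable	-0.3
lonely	-0.4
quiet	-0.6
peaceful	-0.7
mellow	-0.6
smooth	-0.3
subdued	-0.6
stale	-0.3
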