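wonderful	2.7
horrible	-2.5
great	3.1
good	1.9
happy	2.7
love	3.2
loved	2.9
loving	2.9
amazing	2.8
awesome	3.1
excellent	2.7
fantastic	2.6
enjoy	2.2
enjoyed	2.3
enjoying	2.2
fun	2.3
nice	1.8
best	3.2
perfect	2.7
cozy	1.7
sweet	2.0
smooth	1.3
fresh	1.3
tasty	1.9
delicious	2.3
pleasant	1.9
excited	2.4
thrilled	2.7
glad	2.0
beautiful	2.9
friendly	1.9
favorite	2.0
serene	1.6
contented	1.5
relaxed	1.5
relaxing	1.6
calm	1.3
chill	1.2
mellow	1.1
peaceful	1.8
joy	2.9
joyful	2.9
bliss	2.5
paradise	2.9
stoked	2.4
terrible	-2.1
awful	-2.0
bad	-2.5
worst	-3.1
hate	-2.7
hated	-2.6
nasty	-2.2
gross	-1.9
disgusting	-2.4
sad	-2.1
unhappy	-1.8
depressed	-2.3
miserable	-2.6
bored	-1.1
boring	-1.3
annoying	-1.8
angry	-2.3
mad	-2.2
upset	-1.9
stressed	-1.8
tense	-1.2
nervous	-1.5
scared	-1.9
afraid	-1.9
fear	-1.7
harsh	-1.4
stale	-1.2
bitter	-1.4
sick	-1.5
headache	-1.6
trash	-1.9
scam	-2.4
spam	-1.6
fake	-1.6
ripoff	-2.3
waste	-1.6
danger	-1.8
dangerous	-1.9
toxic	-1.9
cancer	-2.4
smelly	-1.6
stinks	-1.8
stink	-1.8
dirty	-1.5
foul	-1.8
unpleasant	-1.7
crap	-2.0
sucks	-1.9
suck	-1.7
disappointing	-1.8
disappointed	-1.8
ruined	-2.1
regret	-1.7
lonely	-1.8
cry	-1.9
hurt	-1.9
pain	-1.9
painful	-2.0
SMILE	2.0
FROWN	-2.2
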