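hookah	noun
hookahs	noun
hooka	noun
shisha	noun
sheesha	noun
sesh	noun
pen	noun
lounge	noun
bar	noun
cafe	noun
flavor	noun
flavors	noun
cloud	noun
clouds	noun
coal	noun
coals	noun
bowl	noun
pipe	noun
tobacco	noun
mint	noun
apple	noun
grape	noun
friend	noun
friends	noun
night	noun
weekend	noun
music	noun
deal	noun
deals	noun
coupon	noun
promo	noun
price	noun
sale	noun
offer	noun
followers	noun
singles	noun
area	noun
session	noun
spot	noun
place	noun
time	noun
vibes	noun
crowd	noun
bliss	noun
headache	noun
cancer	noun
trash	noun
scam	noun
spam	noun
waste	noun
danger	noun
ripoff	noun
crap	noun
joy	noun
fear	noun
pain	noun
paradise	noun
money	noun
bio	noun
smoke	verb
love	verb
hate	verb
enjoy	verb
enjoyed	verb
loved	verb
hated	verb
buy	verb
click	verb
win	verb
taste	verb
tastes	verb
tasted	verb
try	verb
tried	verb
relax	verb
hit	verb
blow	verb
order	verb
ship	verb
follow	verb
miss	verb
cry	verb
hurt	verb
regret	verb
stinks	verb
stink	verb
sucks	verb
suck	verb
ruined	verb
go	verb
going	verb
come	verb
get	verb
got	verb
want	verb
need	verb
feel	verb
felt	verb
know	verb
think	verb
make	verb
check	verb
dm	verb
wonderful	adjective
great	adjective
good	adjective
happy	adjective
amazing	adjective
awesome	adjective
excellent	adjective
fantastic	adjective
fun	adjective
nice	adjective
best	adjective
perfect	adjective
cozy	adjective
sweet	adjective
smooth	adjective
fresh	adjective
tasty	adjective
delicious	adjective
pleasant	adjective
excited	adjective
thrilled	adjective
glad	adjective
beautiful	adjective
friendly	adjective
favorite	adjective
serene	adjective
contented	adjective
calm	adjective
relaxed	adjective
relaxing	adjective
mellow	adjective
peaceful	adjective
chill	adjective
horrible	adjective
terrible	adjective
awful	adjective
bad	adjective
worst	adjective
nasty	adjective
gross	adjective
disgusting	adjective
sad	adjective
unhappy	adjective
depressed	adjective
miserable	adjective
bored	adjective
boring	adjective
annoying	adjective
angry	adjective
mad	adjective
upset	adjective
stressed	adjective
tense	adjective
nervous	adjective
scared	adjective
afraid	adjective
harsh	adjective
stale	adjective
bitter	adjective
sick	adjective
smelly	adjective
dirty	adjective
foul	adjective
unpleasant	adjective
disappointing	adjective
disappointed	adjective
lonely	adjective
painful	adjective
toxic	adjective
dangerous	adjective
fake	adjective
cheap	adjective
new	adjective
old	adjective
big	adjective
small	adjective
hot	adjective
cold	adjective
long	adjective
limited	adjective
guaranteed	adjective
instant	adjective
free	adjective
very	adverb
really	adverb
extremely	adverb
absolutely	adverb
incredibly	adverb
totally	adverb
so	adverb
super	adverb
highly	adverb
completely	adverb
tonight	adverb
today	adverb
now	adverb
always	adverb
never	adverb
much	adverb
too	adverb
fast	adverb
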