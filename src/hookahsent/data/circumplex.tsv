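# emotion	valence	arousal	quadrant	primary
active	0.1305	0.9914	highly_positive	joy
alert	0.3827	0.9239	highly_positive	joy
excited	0.6088	0.7934	highly_positive	joy
elated	0.7934	0.6088	highly_positive	joy
happy	0.9239	0.3827	highly_positive	joy
pleasant	0.9914	0.1305	highly_positive	joy
contented	0.9877	-0.1564	passive_positive	joy
serene	0.891	-0.454	passive_positive	joy
calm	0.7071	-0.7071	passive_positive	joy
relaxed	0.454	-0.891	passive_positive	joy
subdued	0.1564	-0.9877	passive_positive	joy
tense	-0.1564	0.9877	highly_negative	fear
nervous	-0.454	0.891	highly_negative	fear
stressed	-0.7071	0.7071	highly_negative	fear
upset	-0.891	0.454	highly_negative	anger
unpleasant	-0.9877	0.1564	highly_negative	disgust
sad	-0.9808	-0.1951	subdued_negative	sadness
unhappy	-0.8315	-0.5556	subdued_negative	sadness
depressed	-0.5556	-0.8315	subdued_negative	sadness
bored	-0.1951	-0.9808	subdued_negative	sadness
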