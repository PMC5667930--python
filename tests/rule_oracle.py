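"""Independent brute-force enumerator of the valence grammar rules.

Deliberately written as a naive sequential walk over the token stream,
applying each rule by explicit enumeration, so it shares no code with the
production scorer beyond the stemmer used for lexicon fallback lookup.
"""

from hookahsent.stemmer import stem


def oracle_raw_sum(tt, lexicon) -> float:
    tokens = tt.unstemmed
    function_words = lexicon.boosters | lexicon.negators | lexicon.contrast_words

    # locate the first contrast word, if any
    split = None
    for idx in range(len(tokens)):
        if tokens[idx] in lexicon.contrast_words:
            split = idx
            break

    total = 0.0
    for idx in range(len(tokens)):
        word = tokens[idx]
        if word in function_words:
            continue
        if word in lexicon.valences:
            value = lexicon.valences[word]
        elif stem(word) in lexicon.stemmed_valences:
            value = lexicon.stemmed_valences[stem(word)]
        else:
            continue

        doublings = 0
        if idx >= 1 and tokens[idx - 1] in lexicon.boosters:
            doublings += 1
        if tt.allcaps[idx]:
            doublings += 1
        if tt.exclaimed[idx]:
            doublings += 1
        multiplier = float(2 ** doublings)
        if multiplier > 4.0:
            multiplier = 4.0

        negated = False
        back = idx - 1
        while back >= 0 and back >= idx - 3:
            if tokens[back] in lexicon.negators:
                negated = True
            back -= 1
        if negated:
            value = -value

        if split is None:
            clause_weight = 1.0
        elif idx > split:
            clause_weight = 1.5
        else:
            clause_weight = 0.5

        total += value * multiplier * clause_weight
    return total
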