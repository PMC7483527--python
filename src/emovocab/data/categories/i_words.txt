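# emovocab demo category: first-person singular pronouns (synthetic stand-in).
i
me
my
mine
myself
i'm
i've
i'll
i'd
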