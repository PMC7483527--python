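# emovocab demo category: affiliation and social-connection words
# (synthetic stand-in, authored for this package).
friend
friends
friendship
ally
allies
social
together
team
teammate
partner
partners
neighbor
neighbors
community
companion
buddy
buddies
club
belong
belonging
bond
relationship
relationships
roommate
colleague
colleagues
gather
gathering
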