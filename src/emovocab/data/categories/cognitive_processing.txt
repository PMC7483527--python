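# emovocab demo category: cognitive processing words (synthetic stand-in,
# authored for this package; frequency-counted, repeats included).
think
thinks
thinking
thought
thoughts
because
cause
know
knows
knowing
known
knew
reason
reasons
question
questions
wonder
wondering
wondered
consider
considering
considered
realize
realized
realizing
understand
understands
understood
believe
believes
believed
maybe
perhaps
guess
guessing
figure
figured
idea
ideas
decide
decided
deciding
decision
remember
remembered
forget
forgot
mean
means
meaning
meant
why
how
if
whether
should
would
could
sense
logic
logical
conclude
conclusion
assume
assumed
suppose
supposed
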