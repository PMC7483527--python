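# emovocab demo category: first-person plural pronouns (synthetic stand-in).
we
us
our
ours
ourselves
we're
we've
we'll
we'd
let's
lets
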