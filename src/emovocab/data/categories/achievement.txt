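# emovocab demo category: achievement words (synthetic stand-in,
# authored for this package).
win
won
winning
wins
success
successful
succeed
succeeded
better
best
achieve
achieved
achievement
goal
goals
improve
improved
improvement
earn
earned
award
awards
accomplish
accomplished
accomplishment
ambition
ambitious
effort
efforts
master
mastered
excel
triumph
victory
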