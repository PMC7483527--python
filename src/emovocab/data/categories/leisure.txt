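# emovocab demo category: leisure words (synthetic stand-in,
# authored for this package).
cook
cooking
chat
chatting
movie
movies
film
films
game
games
gaming
party
parties
music
concert
band
dance
dancing
vacation
holiday
beach
hike
hiking
camping
fishing
tv
television
show
shows
sport
sports
soccer
basketball
football
tennis
golf
swim
swimming
hobby
hobbies
fun
relax
weekend
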