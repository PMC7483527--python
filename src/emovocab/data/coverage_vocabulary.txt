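# emovocab coverage vocabulary v1.0 (synthetic stand-in, authored for this
# package): a common-English word list used for the "fraction of words
# identifiable" screening criterion and as the filler pool for simulated
# documents. Swappable via configuration.
a
an
the
this
that
these
those
some
any
each
every
no
not
i
me
my
mine
myself
we
us
our
ours
you
your
yours
he
him
his
she
her
hers
it
its
they
them
their
who
what
where
when
why
how
here
there
of
in
on
at
by
for
with
about
against
between
into
through
during
before
after
above
below
to
from
up
down
out
off
over
under
again
then
once
and
but
or
nor
so
yet
if
because
as
until
while
since
than
although
though
both
all
few
more
most
other
such
only
own
same
too
very
just
also
now
ever
never
always
often
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
will
would
shall
should
can
could
may
might
must
don't
didn't
can't
it's
i'm
time
year
day
week
month
hour
minute
moment
morning
evening
night
today
tomorrow
yesterday
people
person
man
woman
child
children
boy
girl
friend
family
mother
father
parent
brother
sister
student
teacher
class
school
college
university
course
lesson
homework
test
exam
grade
book
page
paper
pen
pencil
word
words
sentence
story
letter
note
house
home
room
kitchen
door
window
wall
floor
roof
garden
yard
street
road
city
town
country
world
place
area
side
part
thing
things
way
kind
sort
group
number
amount
lot
bit
piece
end
start
beginning
middle
top
bottom
front
back
left
right
north
south
east
west
water
food
bread
milk
coffee
tea
fruit
apple
orange
rice
meat
fish
egg
sugar
salt
dinner
lunch
breakfast
meal
plate
cup
glass
bottle
table
chair
bed
couch
desk
lamp
light
clock
phone
computer
screen
keyboard
television
radio
music
song
picture
photo
camera
car
bus
train
plane
bike
boat
ship
wheel
engine
trip
travel
journey
walk
run
ride
drive
fly
swim
jump
climb
sit
stand
lie
sleep
wake
rest
work
job
office
business
company
money
dollar
price
cost
pay
buy
sell
shop
store
market
bank
account
hand
head
eye
eyes
ear
nose
mouth
face
hair
arm
leg
foot
feet
finger
heart
mind
body
skin
voice
breath
health
weather
rain
snow
wind
sun
cloud
sky
star
moon
earth
ground
tree
leaf
grass
flower
plant
animal
dog
cat
bird
horse
cow
sheep
mouse
fish
insect
nature
river
lake
sea
ocean
mountain
hill
valley
forest
field
stone
rock
sand
fire
air
go
going
went
gone
come
coming
came
get
getting
got
make
making
made
take
taking
took
give
giving
gave
find
finding
found
think
thinking
thought
know
knowing
knew
known
see
seeing
saw
seen
look
looking
looked
watch
watching
hear
hearing
heard
listen
listening
say
saying
said
tell
telling
told
talk
talking
talked
speak
speaking
spoke
ask
asking
asked
answer
answered
call
calling
called
write
writing
wrote
written
read
reading
learn
learning
learned
teach
taught
study
studying
studied
remember
remembered
forget
forgot
forgotten
understand
understood
believe
believed
feel
feeling
felt
want
wanted
need
needed
like
liked
likes
prefer
choose
chose
chosen
decide
decided
plan
planned
try
trying
tried
use
using
used
help
helping
helped
keep
keeping
kept
hold
holding
held
put
putting
set
setting
turn
turning
turned
move
moving
moved
bring
bringing
brought
carry
carried
send
sending
sent
show
showing
showed
shown
open
opened
close
closed
begin
began
begun
stop
stopped
continue
continued
finish
finished
change
changed
grow
growing
grew
grown
become
became
stay
stayed
leave
leaving
left
arrive
arrived
return
returned
meet
meeting
met
visit
visited
play
played
playing
eat
eating
ate
eaten
drink
drinking
drank
cook
cooked
clean
cleaned
wash
washed
wear
wearing
wore
worn
buy
bought
spend
spent
save
saved
lose
losing
lost
win
winning
won
break
broke
broken
fix
fixed
build
building
built
cut
cutting
draw
drew
drawn
paint
painted
sing
singing
sang
sung
dance
danced
laugh
laughed
smile
smiled
cry
cried
wait
waited
hope
hoped
wish
wished
seem
seemed
appear
appeared
happen
happened
live
living
lived
life
lives
die
died
death
born
good
great
big
large
small
little
long
short
tall
high
low
wide
narrow
deep
shallow
new
old
young
early
late
fast
slow
quick
hot
cold
warm
cool
wet
dry
hard
soft
heavy
light
strong
weak
full
empty
open
closed
clean
dirty
easy
difficult
simple
complex
cheap
expensive
rich
poor
busy
free
quiet
loud
bright
dark
clear
cloudy
sharp
dull
smooth
rough
round
square
flat
straight
near
far
close
distant
different
similar
equal
whole
half
single
double
first
second
third
last
next
final
real
true
false
right
wrong
certain
sure
possible
likely
important
serious
common
rare
usual
strange
normal
special
general
particular
main
major
minor
whole
entire
nice
fine
pretty
beautiful
ugly
interesting
boring
funny
silly
smart
clever
wise
foolish
kind
gentle
polite
rude
honest
fair
careful
careless
brave
shy
lazy
active
healthy
tired
hungry
thirsty
asleep
awake
alive
ready
able
available
enough
several
many
much
little
less
least
plenty
almost
quite
rather
really
truly
maybe
perhaps
probably
certainly
definitely
actually
finally
suddenly
slowly
quickly
quietly
loudly
carefully
easily
hardly
nearly
mostly
together
alone
apart
away
around
along
across
behind
beside
beyond
inside
outside
within
without
instead
however
therefore
anyway
besides
meanwhile
soon
already
still
even
else
again
perhaps
today
thing
stuff
matter
question
problem
reason
cause
result
effect
chance
choice
idea
thought
fact
truth
point
case
example
detail
order
list
line
row
mark
sign
symbol
name
title
game
sport
ball
team
player
score
goal
race
match
park
beach
movie
film
show
stage
theater
concert
party
gift
present
holiday
vacation
weekend
summer
winter
spring
autumn
fall
season
history
science
math
art
color
red
blue
green
yellow
black
white
brown
gray
pink
purple
shape
size
weight
height
length
distance
speed
direction
map
door
key
lock
box
bag
pocket
wallet
watch
ring
shirt
dress
coat
shoe
shoes
hat
glove
button
thread
cloth
towel
soap
mirror
brush
comb
knife
fork
spoon
pan
pot
bowl
oven
fridge
machine
tool
nail
hammer
rope
wire
chain
board
shelf
drawer
basket
bucket
ladder
stairs
elevator
bridge
tunnel
station
airport
hotel
restaurant
hospital
church
library
museum
office
factory
farm
village
neighbor
guest
visitor
stranger
crowd
public
member
leader
boss
worker
doctor
nurse
driver
cook
artist
singer
writer
actor
police
soldier
king
queen
president
government
law
rule
court
peace
war
army
weapon
danger
safety
accident
emergency
news
report
message
email
internet
website
program
system
service
project
plan
budget
meeting
deal
trade
product
brand
customer
client
offer
sale
tax
debt
profit
loss
growth
level
rate
percent
total
sum
average
measure
unit
degree
piece
section
chapter
topic
subject
term
phrase
language
english
speech
conversation
discussion
argument
opinion
advice
suggestion
promise
secret
joke
noise
sound
silence
smell
taste
touch
view
scene
sight
memory
dream
sleep
habit
skill
talent
practice
experience
knowledge
education
training
information
data
record
file
document
form
card
ticket
passport
license
address
phone
number
code
password
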