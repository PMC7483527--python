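# emovocab function-word list v1.0 (synthetic stand-in, authored for this
# package): pronouns, determiners, prepositions, conjunctions, auxiliaries
# and other closed-class words excluded from the open-class type/token ratio.
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
either
neither
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
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
who
whom
whose
which
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
among
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
further
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
whether
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
again
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
ought
i'm
i've
i'll
i'd
you're
you've
you'll
you'd
he's
he'll
he'd
she's
she'll
she'd
it's
it'll
we're
we've
we'll
we'd
they're
they've
they'll
they'd
isn't
aren't
wasn't
weren't
hasn't
haven't
hadn't
doesn't
don't
didn't
won't
wouldn't
shan't
shouldn't
can't
cannot
couldn't
mustn't
let's
that's
there's
what's
who's
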