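# Synthetic stand-in common-word list (role: spell-checker dictionary).
# Doubles as the filler-word pool for the synthetic corpus generator.
able
about
after
again
against
almost
alone
along
already
also
always
another
answer
anyone
anything
appointment
around
asked
away
back
bad
because
been
before
being
believe
best
better
between
big
bit
body
boo
both
breezy
bring
call
came
cannot
care
case
change
check
come
coming
could
crispy
daughter
day
days
decided
definitely
did
different
doctor
does
doing
done
down
during
each
early
eat
else
end
enough
even
ever
every
everyone
everything
exam
experience
family
far
fear
feel
feeling
felt
few
find
fine
first
found
friend
friends
from
get
getting
girl
give
glad
going
gone
good
got
great
had
happy
hard
has
have
having
hear
heard
hello
help
her
here
him
his
home
hope
hoping
hospital
hour
house
how
hugs
hurt
husband
idea
information
into
issue
issues
just
keep
kiddo
kind
knew
know
known
last
late
least
left
less
life
like
little
live
long
look
looking
lot
love
made
make
making
many
may
maybe
mean
might
mind
mine
moment
month
months
more
morning
most
much
must
need
never
new
news
next
nice
night
normal
nothing
now
off
often
okay
old
once
one
only
other
others
our
out
over
own
pain
part
people
place
plan
please
point
post
posted
pretty
probably
problem
put
question
questions
quite
read
reading
really
reason
remember
rest
results
right
said
same
saw
say
saying
scared
see
seems
seen
share
she
side
since
sleep
small
some
someone
something
soon
sorry
sounds
started
stay
still
story
strong
such
sun
support
sure
take
taking
talk
talked
tell
test
tests
than
thank
thanks
that
their
them
then
there
these
they
thing
things
think
thought
three
tiger
time
times
tired
today
together
told
tomorrow
too
took
treatment
tried
trouble
true
try
trying
two
under
until
update
upset
used
very
visit
wait
waiting
want
wanted
was
watch
water
way
week
weeks
well
went
were
what
when
where
which
while
who
whole
why
will
wish
wonder
wonderful
work
worried
worry
worse
would
wrote
year
years
yes
yet
you
your
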