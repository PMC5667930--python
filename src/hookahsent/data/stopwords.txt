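a
an
the
and
or
of
to
in
at
on
for
with
this
that
these
those
is
are
was
were
be
been
being
am
i
you
he
she
it
we
they
me
him
her
us
them
my
your
his
its
our
their
here
there
all
some
any
each
few
more
most
other
such
own
same
than
then
once
during
while
what
which
who
whom
when
where
why
how
do
does
did
doing
have
has
had
having
will
would
shall
can
could
may
might
must
about
against
between
into
through
before
after
above
below
up
down
out
off
again
further
also
just
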