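# Default stoplist for the built-in tokenizer (English function words).
# When a morphological-analyzer adapter is registered for Korean input,
# replace this file with a list of empty morphemes (pre-/postpositions).
a
an
the
and
or
but
if
then
so
of
to
in
on
at
by
for
with
as
is
am
are
was
were
be
been
being
do
does
did
have
has
had
i
me
my
we
our
you
your
he
him
his
she
her
it
its
they
them
their
this
that
these
those
not
no
s
t
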