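# Synthetic stand-in stop-word list (very common English function words).
a
an
and
are
as
at
be
but
by
for
if
in
is
it
no
not
of
on
or
so
the
to
up
we
with
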