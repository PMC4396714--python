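# Closed-vocabulary lexicon for the deterministic fixture tagger.
# token<TAB>Penn tag.  Unknown alphabetic tokens default to NN.
a	DT
an	DT
the	DT
this	DT
these	DT
those	DT
that	DT
each	DT
every	DT
of	IN
in	IN
on	IN
at	IN
by	IN
with	IN
from	IN
for	IN
into	IN
during	IN
without	IN
within	IN
after	IN
before	IN
under	IN
over	IN
between	IN
through	IN
against	IN
about	IN
as	IN
such	IN
per	IN
to	TO
and	CC
or	CC
but	CC
nor	CC
he	PRP
she	PRP
it	PRP
they	PRP
we	PRP
you	PRP
his	PRP$
her	PRP$
its	PRP$
their	PRP$
our	PRP$
your	PRP$
also	RB
not	RB
very	RB
too	RB
then	RB
now	RB
so	RB
however	RB
often	RB
aka	RB
is	VBZ
are	VBP
was	VBD
were	VBD
am	VBP
be	VB
been	VBN
being	VBG
has	VBZ
have	VBP
had	VBD
do	VBP
does	VBZ
did	VBD
can	MD
could	MD
may	MD
might	MD
will	MD
would	MD
shall	MD
should	MD
must	MD
known	VBN
called	VBN
caused	VBN
associated	VBN
referred	VBN
related	VBN
used	VBN
found	VBN
seen	VBN
given	VBN
including	VBG
involving	VBG
containing	VBG
affecting	VBG
sensitive	JJ
specific	JJ
severe	JJ
mild	JJ
moderate	JJ
chronic	JJ
high	JJ
low	JJ
new	JJ
old	JJ
large	JJ
small	JJ
good	JJ
common	JJ
rare	JJ
clear	JJ
assessed	VBD
charted	VBD
checked	VBD
cited	VBD
claimed	VBD
cleared	VBD
coded	VBD
collected	VBD
compared	VBD
compiled	VBD
completed	VBD
computed	VBD
counted	VBD
covered	VBD
created	VBD
dated	VBD
defined	VBD
delivered	VBD
detailed	VBD
detected	VBD
determined	VBD
discussed	VBD
documented	VBD
drafted	VBD
entered	VBD
estimated	VBD
evaluated	VBD
examined	VBD
expected	VBD
explained	VBD
filed	VBD
filled	VBD
finished	VBD
flagged	VBD
followed	VBD
formed	VBD
gathered	VBD
graded	VBD
grouped	VBD
handled	VBD
indexed	VBD
inspected	VBD
joined	VBD
judged	VBD
labeled	VBD
listed	VBD
located	VBD
logged	VBD
mapped	VBD
marked	VBD
matched	VBD
measured	VBD
mentioned	VBD
merged	VBD
monitored	VBD
named	VBD
noticed	VBD
numbered	VBD
obtained	VBD
opened	VBD
ordered	VBD
outlined	VBD
paired	VBD
parsed	VBD
passed	VBD
performed	VBD
placed	VBD
planned	VBD
plotted	VBD
pooled	VBD
posted	VBD
prepared	VBD
printed	VBD
processed	VBD
produced	VBD
profiled	VBD
quantified	VBD
queried	VBD
ranked	VBD
rated	VBD
reached	VBD
recorded	VBD
reduced	VBD
registered	VBD
rehearsed	VBD
rendered	VBD
repeated	VBD
rephrased	VBD
resolved	VBD
restated	VBD
resulted	VBD
retained	VBD
returned	VBD
reviewed	VBD
revised	VBD
sampled	VBD
saved	VBD
scanned	VBD
scheduled	VBD
scored	VBD
screened	VBD
searched	VBD
secured	VBD
selected	VBD
sequenced	VBD
shared	VBD
shifted	VBD
signed	VBD
sketched	VBD
solved	VBD
sorted	VBD
stored	VBD
studied	VBD
submitted	VBD
summarized	VBD
supplied	VBD
surveyed	VBD
tabulated	VBD
tallied	VBD
targeted	VBD
tested	VBD
totaled	VBD
traced	VBD
tracked	VBD
trained	VBD
transcribed	VBD
treated	VBD
updated	VBD
verified	VBD
viewed	VBD
weighed	VBD
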