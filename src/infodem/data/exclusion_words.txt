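# Common English nouns, verbs, and adjectives excluded from bare
# place-name matching (editable stand-in for full top-1000 per-language
# lists).  One word per line; lines starting with # are kept out by the
# loader because they contain no bare word token.
time year people way day man thing woman life child world school state
family student group country problem hand part place case week company
system program question work government number night point home water
room mother area money story fact month lot right study book eye job
word business issue side kind head house service friend father power
hour game line end member law car city community name president team
minute idea kid body information back parent face others level office
door health person art war history party result change morning reason
research girl guy moment air teacher force education be have do say get
make go know take see come think look want give use find tell ask seem
feel try leave call good new first last long great little own other old
big high different small large next early young important few public bad
same able park mobile nice industry field major view main general strong
free true federal open close full special easy clear recent certain
personal plan run move live believe hold bring happen write provide sit
stand lose pay meet include continue set learn lead understand watch
follow stop create speak read allow add spend grow win offer remember
love consider appear buy wait serve die send expect build stay fall cut
reach kill remain suggest raise pass sell require report decide pull
real best better sure low late hard past possible available likely short
single medical current wrong private past foreign fine common poor
natural significant similar hot dead central happy serious ready simple
left physical general environmental financial blue democratic dark
various entire close legal religious cold final green nice huge popular
traditional cultural union spring fair independence
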