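term	variants	present_in_corpus
edibles		1
weed	weeed,weeeeed	1
ganja	ganj	1
kush	kushy,og_kush,bubba_kush,khalifa_kush	1
sativa		1
sour_diesel		1
indica		1
devil's_lettuce	devils_lettuce	1
dro		1
dabs		1
purp		1
pot		1
dank	danky	1
herb		1
reggie		1
wax		1
nug		1
mary_jane		1
pineapple_express		1
chronic		1
shatter		1
bud		1
skunk		1
haze		1
exotics		1
hydro		1
shard		1
flower		1
fire		1
mud		1
flame		1
green		1
sour_d		0
blue_cheese		0
love_boat		0
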