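term	category
# synthetic stand-in: only the marijuana-category terms are the attested candidates; other rows are placeholders
kush	marijuana
reefer	marijuana
dro	marijuana
reefa	marijuana
weed	marijuana
sativa	marijuana
sour_diesel	marijuana
purp	marijuana
devils_lettuce	marijuana
og_kush	marijuana
doja	marijuana
kief	marijuana
gorilla_glue	marijuana
thrax	marijuana
piff	marijuana
weeed	marijuana
moonrocks	marijuana
pacc	marijuana
tookah	marijuana
devil's_lettuce	marijuana
moonrock	marijuana
tooka	marijuana
edibles	marijuana
mids	marijuana
bubba_kush	marijuana
gasss	marijuana
gass	marijuana
marijuana	marijuana
ganj	marijuana
dodi	marijuana
indica	marijuana
jazz_cabbage	marijuana
faygo	marijuana
dank	marijuana
dabs	marijuana
oregano	marijuana
wata	marijuana
bammer	marijuana
tincture	marijuana
marijuanas	marijuana
k2	marijuana
thc	marijuana
gas	marijuana
rosin	marijuana
smarties	marijuana
pot	marijuana
🍃_🍃	marijuana
gassss	marijuana
danky	marijuana
hemp	marijuana
weeeeed	marijuana
herb	marijuana
kool_aid	marijuana
hawaiian_punch	marijuana
cannabis	marijuana
reggie	marijuana
jolly_ranchers	marijuana
kushy	marijuana
grape_juice	marijuana
cheech	marijuana
goop	marijuana
khalifa_kush	marijuana
tropical_fusion	marijuana
broccoli	marijuana
medicinal	marijuana
doobie	process_or_paraphernalia
blunts	process_or_paraphernalia
bong_rips	process_or_paraphernalia
para00	process_or_paraphernalia
para01	process_or_paraphernalia
para02	process_or_paraphernalia
para03	process_or_paraphernalia
para04	process_or_paraphernalia
para05	process_or_paraphernalia
para06	process_or_paraphernalia
para07	process_or_paraphernalia
para08	process_or_paraphernalia
para09	process_or_paraphernalia
para10	process_or_paraphernalia
para11	process_or_paraphernalia
para12	process_or_paraphernalia
para13	process_or_paraphernalia
para14	process_or_paraphernalia
para15	process_or_paraphernalia
para16	process_or_paraphernalia
para17	process_or_paraphernalia
para18	process_or_paraphernalia
para19	process_or_paraphernalia
para20	process_or_paraphernalia
para21	process_or_paraphernalia
para22	process_or_paraphernalia
para23	process_or_paraphernalia
para24	process_or_paraphernalia
para25	process_or_paraphernalia
para26	process_or_paraphernalia
para27	process_or_paraphernalia
para28	process_or_paraphernalia
para29	process_or_paraphernalia
para30	process_or_paraphernalia
para31	process_or_paraphernalia
para32	process_or_paraphernalia
para33	process_or_paraphernalia
para34	process_or_paraphernalia
para35	process_or_paraphernalia
para36	process_or_paraphernalia
para37	process_or_paraphernalia
para38	process_or_paraphernalia
para39	process_or_paraphernalia
para40	process_or_paraphernalia
para41	process_or_paraphernalia
para42	process_or_paraphernalia
para43	process_or_paraphernalia
para44	process_or_paraphernalia
para45	process_or_paraphernalia
para46	process_or_paraphernalia
opium	other_drug
shrooms	other_drug
mdma	other_drug
cocaine	other_drug
othr00	other_drug
othr01	other_drug
othr02	other_drug
othr03	other_drug
othr04	other_drug
othr05	other_drug
othr06	other_drug
othr07	other_drug
othr08	other_drug
othr09	other_drug
othr10	other_drug
othr11	other_drug
othr12	other_drug
othr13	other_drug
othr14	other_drug
othr15	other_drug
othr16	other_drug
othr17	other_drug
othr18	other_drug
othr19	other_drug
othr20	other_drug
othr21	other_drug
othr22	other_drug
othr23	other_drug
othr24	other_drug
othr25	other_drug
othr26	other_drug
othr27	other_drug
othr28	other_drug
othr29	other_drug
othr30	other_drug
othr31	other_drug
othr32	other_drug
othr33	other_drug
othr34	other_drug
othr35	other_drug
othr36	other_drug
othr37	other_drug
othr38	other_drug
othr39	other_drug
othr40	other_drug
othr41	other_drug
othr42	other_drug
othr43	other_drug
othr44	other_drug
othr45	other_drug
othr46	other_drug
othr47	other_drug
othr48	other_drug
othr49	other_drug
othr50	other_drug
othr51	other_drug
othr52	other_drug
rasta	nondrug
catnip	nondrug
herbal	nondrug
nond00	nondrug
nond01	nondrug
nond02	nondrug
nond03	nondrug
nond04	nondrug
nond05	nondrug
nond06	nondrug
nond07	nondrug
nond08	nondrug
nond09	nondrug
nond10	nondrug
nond11	nondrug
nond12	nondrug
nond13	nondrug
nond14	nondrug
nond15	nondrug
nond16	nondrug
nond17	nondrug
nond18	nondrug
nond19	nondrug
nond20	nondrug
nond21	nondrug
nond22	nondrug
nond23	nondrug
nond24	nondrug
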