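form	kind	glosses
# Greek/Latin combining forms (body parts and substances)
cardi	combining	heart
cardio	combining	heart
neur	combining	nerve|nervous
neuro	combining	nerve|nervous
hepat	combining	liver
hepato	combining	liver
nephr	combining	kidney
nephro	combining	kidney
ren	combining	kidney
gastr	combining	stomach
gastro	combining	stomach
enter	combining	intestine|intestinal
entero	combining	intestine|intestinal
col	combining	colon
colo	combining	colon
derm	combining	skin
dermat	combining	skin
dermato	combining	skin
oste	combining	bone
osteo	combining	bone
arthr	combining	joint
arthro	combining	joint
my	combining	muscle
myo	combining	muscle
encephal	combining	brain
encephalo	combining	brain
cerebr	combining	brain
cerebro	combining	brain
pneum	combining	lung
pneumo	combining	lung
pulmon	combining	lung
pulmono	combining	lung
bronch	combining	airway|bronchial
broncho	combining	airway|bronchial
rhin	combining	nose|nasal
rhino	combining	nose|nasal
ot	combining	ear
oto	combining	ear
ophthalm	combining	eye
ophthalmo	combining	eye
ocul	combining	eye
angi	combining	vessel|vascular
angio	combining	vessel|vascular
vascul	combining	vessel|vascular
arteri	combining	artery|arterial
arterio	combining	artery|arterial
phleb	combining	vein
phlebo	combining	vein
haem	combining	blood
haemo	combining	blood
haemat	combining	blood
haemato	combining	blood
hem	combining	blood
hemo	combining	blood
hemat	combining	blood
hemato	combining	blood
leuk	combining	white cell
leuko	combining	white cell
erythr	combining	red cell
erythro	combining	red cell
thromb	combining	clot
thrombo	combining	clot
cyt	combining	cell
cyto	combining	cell
aden	combining	gland
adeno	combining	gland
lymph	combining	lymph
lympho	combining	lymph
splen	combining	spleen
spleno	combining	spleen
pancreat	combining	pancreas
pancreato	combining	pancreas
cholecyst	combining	gallbladder
chol	combining	bile
chole	combining	bile
cyst	combining	bladder
cysto	combining	bladder
mening	combining	meninges|meningeal
meningo	combining	meninges|meningeal
myel	combining	marrow|spinal cord
myelo	combining	marrow|spinal cord
spondyl	combining	vertebra|spinal
spondylo	combining	vertebra|spinal
chondr	combining	cartilage
chondro	combining	cartilage
mast	combining	breast
masto	combining	breast
hyster	combining	uterus|uterine
hystero	combining	uterus|uterine
orchi	combining	testis
prostat	combining	prostate
thyroid	combining	thyroid
glyc	combining	sugar
glyco	combining	sugar
lip	combining	fat
lipo	combining	fat
calc	combining	calcium
kal	combining	potassium
natr	combining	sodium
ferr	combining	iron
path	combining	disease
psych	combining	mind|mental
psycho	combining	mind|mental
# disorder affixes
pathy	suffix	disease
itis	suffix	inflammation
osis	suffix	disease|degeneration
iasis	suffix	condition
emia	suffix	blood abnormality|blood
aemia	suffix	blood abnormality|blood
algia	suffix	pain
dynia	suffix	pain
megaly	suffix	enlargement
penia	suffix	deficiency
oma	suffix	tumor|tumour
ectasis	suffix	dilation
plegia	suffix	paralysis
paresis	suffix	weakness
rrhage	suffix	bleeding
rrhagia	suffix	bleeding
rrhea	suffix	discharge
rrhoea	suffix	discharge
sclerosis	suffix	hardening
stenosis	suffix	narrowing
malacia	suffix	softening
ptosis	suffix	drooping
trophy	suffix	growth
dystrophy	suffix	abnormal growth
lysis	suffix	breakdown
spasm	suffix	spasm
# modifier prefixes
hyper	prefix	excessive|high
hypo	prefix	deficient|low
a	prefix	without
an	prefix	without
dys	prefix	impaired|abnormal
brady	prefix	slow
tachy	prefix	rapid
macro	prefix	large
micro	prefix	small
poly	prefix	many
pan	prefix	all
peri	prefix	around
endo	prefix	inner
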