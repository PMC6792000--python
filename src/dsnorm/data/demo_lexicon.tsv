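# Demonstration lexicon for the supplement product-name tagger.
# Columns (tab-separated): surface, canonical, term_type, source.
#   surface    — the keyword as it may appear in a name (matched
#                case-insensitively; stored lowercased)
#   canonical  — preferred form used in normalized output (defaults to
#                the surface when empty)
#   term_type  — one of the 14 term-type codes
#   source     — provenance label for auditing (which terminology or
#                curation pass the keyword came from)
# This file is a small hand-curated stand-in for the full keyword lists
# (brand annotations, an ingredient thesaurus, dose-form / plant-part /
# preparation vocabularies); it covers common single-ingredient
# supplement names and every worked example in the documentation.
#
# --- Brand names (manually curated) ---
herb pharm	Herb Pharm	BN	annotation
bronson laboratories	Bronson Laboratories	BN	annotation
nutrabio	NutraBio	BN	annotation
terravita	TERRAVITA	BN	annotation
optimum nutrition	Optimum Nutrition	BN	annotation
nature's answer	Nature's Answer	BN	annotation
nature made	Nature Made	BN	annotation
jarrow formulas	Jarrow Formulas	BN	annotation
now foods	NOW Foods	BN	annotation
solgar	Solgar	BN	annotation
gnc	GNC	BN	annotation
physician's preference	Physician's Preference	BN	annotation
# --- Ingredients (thesaurus-style) ---
elderberry	Elderberry	IN	iDISK
melatonin	Melatonin	IN	iDISK
potassium citrate	Potassium Citrate	IN	iDISK
tribulus	Tribulus	IN	iDISK
hawthorn	Hawthorn	IN	iDISK
magnesium	Magnesium	IN	iDISK
green tea	Green Tea	IN	iDISK
ginkgo biloba	Ginkgo Biloba	IN	iDISK
turmeric	Turmeric	IN	iDISK
fish oil	Fish Oil	IN	iDISK
garlic	Garlic	IN	iDISK
zinc	Zinc	IN	iDISK
echinacea	Echinacea	IN	iDISK
peppermint	Peppermint	IN	iDISK
ashwagandha	Ashwagandha	IN	iDISK
cayenne	Cayenne	IN	iDISK
# --- Dose forms ---
powder	Powder	DF	TGA
capsule	Capsule	DF	TGA
tablet	Tablet	DF	TGA
softgel	Softgel	DF	TGA
lozenge	Lozenge	DF	TGA
liquid	Liquid	DF	TGA
spray	Spray	DF	TGA
# --- Dose form groups ---
topical	Topical	DFG	TGA
oral	Oral	DFG	TGA
chewable	Chewable	DFG	TGA
# --- Plant parts ---
berry	Berry	PLNT	TGA
leaf	Leaf	PLNT	TGA
root	Root	PLNT	TGA
seed	Seed	PLNT	TGA
flower	Flower	PLNT	TGA
bark	Bark	PLNT	TGA
# --- Preparations ---
extract	Extract	PREP	TGA
dried	Dried	PREP	TGA
raw	Raw	PREP	TGA
fermented	Fermented	PREP	TGA
concentrate	Concentrate	PREP	TGA
# --- Animal sources ---
bone marrow	Bone Marrow	ANM	TGA
liver	Liver	ANM	TGA
heart	Heart	ANM	TGA
cartilage	Cartilage	ANM	TGA
# --- Flavors ---
strawberry	Strawberry	FLV	annotation
lemon	Lemon	FLV	annotation
orange	Orange	FLV	annotation
vanilla	Vanilla	FLV	annotation
chocolate	Chocolate	FLV	annotation
# --- Populations ---
children's	Children's	POP	TGA
women's	Women's	POP	TGA
men's	Men's	POP	TGA
adult	Adult	POP	TGA
senior	Senior	POP	TGA
# --- Certifications ---
usp certified	USP Certified	CERT	TGA
organic	Organic	CERT	TGA
non-gmo	Non-GMO	CERT	TGA
kosher	Kosher	CERT	TGA
# --- Times of use ---
night time	Night Time	TIM	TGA
nighttime	Night Time	TIM	TGA
morning	Morning	TIM	TGA
bedtime	Bedtime	TIM	TGA
# --- Claims / uses ---
sleep aid	Sleep Aid	USE	annotation
immune support	Immune Support	USE	annotation
energy	Energy	USE	annotation
joint support	Joint Support	USE	annotation
stress relief	Stress Relief	USE	annotation
# --- Stop words ---
with		STOP	annotation
and		STOP	annotation
the		STOP	annotation
of		STOP	annotation
for		STOP	annotation
natural		STOP	annotation
plus		STOP	annotation
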