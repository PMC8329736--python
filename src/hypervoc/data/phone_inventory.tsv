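# Phone inventory for infant-vocalization transcriptions (Swedish).
# Columns: symbol<TAB>category<TAB>classes (comma-separated, may be empty)<TAB>notes
# Categories: consonant | vowel. Length: "ː" on a vowel is handled by the
# parser; a long vowel inherits its base symbol's row unless an explicit
# long-vowel row exists below (the long front rounded set).
symbol	category	classes	notes
p	consonant		bilabial plosive
b	consonant		bilabial plosive
t	consonant		dental plosive
d	consonant		dental plosive
ʈ	consonant		retroflex plosive; source table garbled (printed as plain t)
ɖ	consonant		retroflex plosive
k	consonant	velar	velar plosive
g	consonant	velar	velar plosive
m	consonant		bilabial nasal
n	consonant		dental nasal
ɳ	consonant		retroflex nasal
ŋ	consonant	velar	velar nasal
r	consonant	trill	alveolar trill
ʀ	consonant	trill	uvular trill; source table prints [r] twice, uvular cell assumed ʀ
ɾ	consonant		alveolar tap
f	consonant	fricative	labiodental fricative
v	consonant	fricative,voiced-fricative	labiodental fricative
s	consonant	fricative	dental fricative
ʂ	consonant	fricative	retroflex fricative
ʐ	consonant	fricative,voiced-fricative	retroflex fricative
ʝ	consonant	fricative,voiced-fricative	palatal fricative
ʁ	consonant	fricative,voiced-fricative	uvular fricative
h	consonant	fricative	glottal fricative
ɧ	consonant	velar,fricative	velar+fricative; listed in the scoring classes though absent from the consonant chart
ɕ	consonant	fricative	alveolo-palatal fricative; listed in the scoring classes though absent from the consonant chart
ɹ	consonant	liquid	alveolar approximant
l	consonant	liquid	lateral approximant
ɭ	consonant	liquid	retroflex lateral approximant
j	consonant		palatal approximant
i	vowel		close front unrounded
y	vowel		close front rounded
ʉ	vowel		close central rounded
u	vowel		close back rounded
e	vowel		close-mid front unrounded
ø	vowel		close-mid front rounded
o	vowel		close-mid back rounded
ɛ	vowel		open-mid front unrounded
œ	vowel		open-mid front rounded
ɔ	vowel		open-mid back rounded
a	vowel		open front unrounded
ɑ	vowel		open back unrounded
æ	vowel		near-open front unrounded
ə	vowel		mid central
ɪ	vowel		near-close front unrounded
ʏ	vowel		near-close front rounded
ʊ	vowel		near-close back rounded
ɵ	vowel		close-mid central rounded
yː	vowel	long-front-rounded-vowel	long close front rounded
øː	vowel	long-front-rounded-vowel	long close-mid front rounded
ʉː	vowel	long-front-rounded-vowel	long close central rounded; third member of the truncated source list, assumed — override via a custom inventory file
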