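# Methods

This note documents the models and conventions `hypervoc` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where the conventions in
the literature are underspecified.

## Transcription parsing

Transcriptions are single Unicode IPA symbols over a configurable
inventory (shipped as `data/phone_inventory.tsv`: Swedish consonants
and vowels plus common allophones). Dialect conventions:

- `.` separates syllables; `ˈ` (ASCII `'` accepted) marks the following
  syllable as carrying primary stress; a grave/acute accent diacritic on
  a vowel (`mà.ma`) marks that vowel's syllable stressed. Both stress
  notations occur in practice; both are accepted and normalized to `ˈ`
  on output. At most one primary stress is allowed per vocalization.
- `ː` (ASCII `:` accepted) attaches to the preceding vowel; length is a
  property of the phone and is required for the long-front-rounded
  vowel class.
- `C` / `V` mark segments identifiable only as consonant-like /
  vowel-like; they count for syllable structure (clusters, codas,
  nuclei) but earn no sound-class points. `□` (indeterminate) counts
  for nothing, not even cluster membership — a deliberately
  conservative treatment of uncertain material.
- If a string has no syllable delimiters but several vowel nuclei, it
  is syllabified deterministically: one syllable per nucleus, with all
  intervening consonants assigned to the following onset (onset
  maximization with every inventory consonant sequence admitted as an
  onset). This keeps undelimited corpus files scoreable; explicitly
  delimited input is never second-guessed.

Serialization to the canonical dialect is a fixed point of
parse∘serialize, which the tests check on randomly generated strings.

Two inventory cells in the source consonant chart are typographically
ambiguous; the shipped file documents the resolution (retroflex plosive
`ʈ`, uvular trill `ʀ`) in its notes column, and the third member of the
long front rounded set (`ʉː`) is likewise a documented, overridable
assumption.

Inter-transcriber agreement is computed as matched characters under an
optimal global alignment (longest common subsequence with exact
character match) divided by the longer string's length, ×100. This is
the simplest symmetric reading of "percentage of matching characters";
other alignment costs could be substituted without touching callers.

## WCM-SE scoring

Ten parameters in three domains: >2 syllables (1/vocalization),
non-initial stress (1/vocalization), word-final consonant
(1/vocalization), consonant cluster (1/occurrence), velar, liquid,
fricative, voiced fricative (1/occurrence each), trill (3/occurrence),
long front rounded vowel (1/occurrence). Conventions where the measure
leaves room:

- *Cluster* = maximal run of ≥2 consecutive consonantal phones anywhere
  in the vocalization, ignoring syllable boundaries, one point per run
  regardless of length. This matches the single "nt" cluster point in
  the trisyllabic worked example; a `tautosyllabic_clusters` flag
  restricts runs to within syllables for users who prefer that reading.
- *Word* = vocalization: vocalization boundaries are silence-based, so
  the word-final-consonant parameter applies to the final phone of the
  whole vocalization.
- A phone in several classes earns points for each ([v] = fricative +
  voiced fricative = 2; [ɧ] = velar + fricative = 2).
- Non-initial stress requires an explicit stress mark; segmental
  content never implies stress. Initial accent (accent-II-style `mà`)
  counts as initial stress and earns nothing.

The scorer is validated against an independent character-level recount
on 1,000 random vocalizations per test run.

## Vowel space area

Tokens with median f0 strictly above the ceiling (default 350 Hz,
where formant estimation becomes unreliable) are excluded; a median of
exactly 350 Hz is kept. Each remaining token contributes the mean of
the formant samples whose timestamps fall in the closed central window
[t₀ + 0.3·d, t₀ + 0.7·d] (the mid 40% of the vowel, reducing
coarticulation bias at the edges); inclusion is by timestamp rather
than sample index so unevenly sampled tracks are handled correctly,
and a track with no sample in the window falls back to the sample
nearest the midpoint. Pre-averaged tokens (point F1/F2 without a
track) bypass windowing.

Per-vowel means are unweighted token averages (token-level windowed
mean first, then across tokens). The VSA is the absolute triangle
area of the three mean points — algebraically the shoelace formula —
and the hyperarticulation measure is the signed difference
VSA_IDS − VSA_ADS (negative values indicate hypoarticulation and are
preserved).

Bark analysis converts each token's F1/F2 with
z = 26.81·f/(1960 + f) − 0.53 (corrections z<2: z + 0.15·(2−z);
z>20.1: z + 0.22·(z−20.1)) *before* averaging, then proceeds
identically. The transform is config-swappable.

## Group analysis

Registers are compared with a classical two-tailed paired-samples
t-test on per-speaker areas (df = n − 1); zero-variance differences
are a hard error, not a silent NaN. The association between parental
adaptation and infant complexity is OLS of per-subject mean WCM-SE on
VSA difference with an intercept, reporting the slope β, the F-test of
the slope (df (1, n − 2)), R² and p. The effect-size report
β × 10,000 expresses the predicted score change per 10,000 Hz² of VSA
difference (display-rounded to 2 decimals next to full precision).

Subject outlier policies: `none`; `absolute(cutoff)`; default `z(k=3)`
computed leave-one-out (a subject is excluded when it deviates from
the mean of the others by more than k of their SDs). The leave-one-out
form keeps an extreme point from masking itself in its own criterion.
Every exclusion is logged with its reason, and the same exclusion set
is applied to the Hz and Bark regressions.

## Synthetic data generator

The generator emulates the *statistical* structure the analysis
assumes, not speech itself:

- **Acoustics.** Speaker ADS point-vowel means are drawn around
  published grand means for Swedish parents (/i/ 472/1904, /ɑ/
  661/1307, /u/ 473/1032 Hz) with between-speaker SDs of 60 (F1) and
  150 (F2) Hz; within-speaker token SDs default to 60/170 Hz, chosen
  so that pooled token spread lands near published descriptive SDs.
  The IDS triangle is the speaker's ADS triangle expanded **linearly**
  about its centroid by `expansion_factor` (default 1.36; area scales
  with the square), plus register jitter — expansion about the
  centroid isolates area change from translation of the vowel space.
  Tracks are sampled at 6.25 ms steps over 80–250 ms with linear onset
  and offset ramps (default 25% of duration each) from a neutral locus
  (500, 1500 Hz), so mid-window averaging is genuinely exercised;
  median f0 straddles the 350 Hz ceiling at a configurable exceedance
  rate (default 10%).
- **Complexity.** Each vocalization starts as a zero-scoring CV.CV
  frame; independent Bernoulli features inject exactly one parameter
  each (trill/liquid/fricative/velar/voiced-fricative onsets, a
  cluster, a final consonant, a third syllable, second-syllable
  stress, a long front rounded nucleus). The expected score given
  feature probabilities is available in closed form — the only
  coupling, an extra cluster point when ≥2 sound-class onsets co-occur
  in one run, is handled by inclusion–exclusion — so probabilities are
  calibrated exactly (bisection on the common scale factor) to any
  reachable target mean; unreachable targets raise.
- **Linkage.** Each infant's target mean score is
  intercept + β_true × (true VSA difference) + Gaussian noise
  (defaults 1.0, 8e-6, 0.42 — residual scale consistent with observed
  between-subject spread), floored at zero; the corpus (default 30
  vocalizations, roughly a 10-minute session) is generated at that
  target. The fitted regression slope is therefore an estimator of
  β_true, and the tests check it is unbiased across replicates.

What the generator does **not** emulate: real coarticulation dynamics
(ramps are linear and symmetric), f0–formant covariation, vowel
category confusability, transcriber disagreement, serial dependence
within a session, or turn-level contingency between parent and infant.
Passing tests therefore demonstrate that the *pipeline* is correct and
well-calibrated under its stated assumptions, not that those
assumptions hold in any particular corpus.

All randomness flows through one explicitly passed
`numpy.random.Generator`; equal seeds give byte-identical datasets and
reports.

## Problem sizes used in validation

End-to-end statistical checks run at study scale: detection of the
register effect uses 100 replicates of 19-dyad studies at default
(realistic) noise; slope recovery uses 100 replicates of 200-dyad
low-noise studies (within-speaker SD 5 Hz, 10 tokens per vowel per
register, 12 vocalizations per infant, residual SD 0.1), sizes chosen
to make bias visible above Monte Carlo error while keeping the default
test run in the minutes range. Kernel-level oracle checks (shoelace
area, flat score recount, window-bias comparison) use 1,000 random
cases each.

## Known limitations

- Only the three-vowel (triangle) VSA is supported; quadrilateral
  spaces with /æ/ or similar are out of scope.
- Formant estimation itself (LPC from audio) is out of scope; the
  package consumes formant tracks or point estimates.
- The syllabification fallback is intentionally naive (all consonants
  to the onset); language-specific phonotactics would change syllable
  counts only for undelimited input.
- The TextGrid reader handles the long text format only; short-format
  files should be converted or supplied as TSV.
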