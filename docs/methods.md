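# Methods

## Pseudo-language generation

A pseudo-language is four trisyllabic CV words. Two constraint profiles are
implemented. The `EXP1` profile draws on 4 vowels (a, u, i, o) and 7
consonants (p, t, k, b, d, g, n) and forbids repeated syllables within a
word. The `EXP2` profile draws on 5 vowels and 13 consonants (6 stops, 3
fricatives, 4 sonorants) and is much tighter: no vowel repeats within a word,
no consonant repeats within a language (so all 12 syllables are unique), and
the 12 vowel slots realize the multiset {3, 3, 2, 2, 2} over the five vowels.
Four-language sets additionally require that no syllable appears in more than
two of the languages, which blocks transfer of item knowledge between
conditions in within-subjects designs.

Generation is rejection sampling over uniformly drawn candidate words,
accepted one at a time against the constraints accumulated so far. Word-level
(rather than whole-language) rejection is necessary because the probability
that four independent words jointly use 12 distinct consonants is ~3·10⁻⁶.
A completability check prevents dead ends: after each accepted word the
per-vowel counts must still be extendable to {3, 3, 2, 2, 2} by the remaining
words, where each word can add at most one token of any vowel (checked by
enumerating the 10 distinct assignments of the target multiset to the five
vowels). The whole-language validator remains the single source of truth; the
generator's incremental checks are an optimization and every generated
language is re-validated before being returned. Word lists can be screened
against a caller-supplied blocklist (e.g. real German/English words); no
lexicon is bundled.

## Stream composition

Streams concatenate the four words with two restrictions: no immediate
repetition, and each word followed by each other word "equally often". With
T transitions over 12 ordered pairs, and T = 39 (40-word streams) or 95
(96-word streams) not divisible by 12, exact equality is unachievable;
"equally often" is implemented as maximal balance (every pair count ⌊T/12⌋ or
⌈T/12⌉). The generator is a randomized greedy walk — next word chosen among
non-repeating candidates with remaining uses, preferring the least-used
ordered pair, ties broken uniformly — restarted until the balance invariant
holds (typically a handful of restarts; the cap is 1,000).

Transitional probabilities follow the standard forward bigram convention
P(next | current); the stream-final syllable contributes no outgoing
transition and denominators count antecedent occurrences with a successor.
Because every syllable occurs in exactly one word position of one word,
within-word TPs are exactly 1.0 on every stream, and balance pins the mean
between-word TP to 1/3 up to the ±1-count granularity.

## Prosodic conditions

All syllables are normalized to 500 ms and 210 Hz (a deliberately slow 2
syllables/s). The five cue conditions change word-final syllables only:
250 ms silent pause after them, duration 750 ms (+50%) or 250 ms (−50%), or
f0 260 Hz or 160 Hz (±50 Hz). Durations and frequencies are stored as exact
integers; no jitter is modelled. The pause is emitted after every word
including the last, which makes the closed-form totals exact: 40-word streams
last 50/60/70 s (shortening / baseline & pitch / pause & lengthening) and
96-word streams 120/144/168 s.

The fade-in/out raises the first 15 syllables in steps of exactly 1/15 of
peak amplitude (the printed 6.66% is 1/15 rounded; using 1/15 lands the 16th
syllable at exactly full amplitude with no residue) and mirrors this over the
last 15, so stream edges do not mark word boundaries.

## Audio rendering

The original study used recorded human syllables resynthesized with PSOLA.
Here syllables are synthesized parametrically: a 20 ms broadband noise burst
(the consonant onset) followed by a harmonic complex at the token's f0 with
1/h harmonic rolloff and 5 ms raised-cosine edges. The burst is never
time-scaled — durational manipulations act on the voiced remainder only,
mirroring the original's protection of the first 20 ms against voice-onset
shifts — and is bit-identical across durational conditions. The voiced
portion is peak-normalized to 1.0 and the burst to 0.8, so each syllable's
peak is exactly `0.99 × amp_scale`. f0 is constant within a token (the
micro-intonation of natural syllables is not modelled). Output is 16-bit PCM
mono WAV plus a JSON manifest of half-open sample intervals per segment,
which makes segment timing verifiable sample-exactly. Pauses are digital
silence. The rendering exists to make the acoustic contract of the symbolic
stream concrete; it makes no claim to naturalness (no formant structure,
coarticulation, or speaker identity).

## Test items

Every ordered word pair (A, B), A ≠ B, yields one part-word per class —
class 1-2: final(A) + initial(B) + medial(B); class 2-1: medial(A) + final(A)
+ initial(B) — i.e. 12 per class for a 4-word language. A test set is 4 words
+ 4 part-words per class. The within-subjects selection constraint ("each
first and second part represented once per class") is formalized as a
derangement σ of the word indices (item i combines word i's part with word
σ(i)'s part, σ(i) ≠ i); there are exactly 9 derangements of 4 elements and
the selector samples them uniformly. The fixed pilot test set is reproduced
verbatim and deliberately violates this constraint (one second-part appears
twice), as in the original design. Test items are rendered, when rendered at
all, with baseline parameters: they carry no prosodic modification.

## Simulated listeners

Human judgments are replaced by a Bernoulli response model on the logit
scale: participant j has a latent offset u_j ~ Normal(0, σ_subject), and the
probability of calling a stimulus of type s in condition c a "word" is
sigmoid(logit(p_word[c, s]) + u_j). Each of the 12 trials per condition is an
independent draw. This is the simplest generative model compatible with a
logistic random-intercept analysis. A judgment is *correct* when a
statistical word is accepted or a part-word rejected, so chance is 50%
correct for every stimulus type.

Three layouts reproduce the three designs' arithmetic exactly: between-
subjects (202 participants, group sizes 34/33/33/34/33/35 over the six
conditions → 2,424 judgments), within-subjects over four conditions (34 × 4
× 12 = 1,632), and within-subjects over four of six conditions — baseline,
pause, one durational, one pitch condition, the 2×2 durational-by-pitch
assignment balanced to ~n/4 (42 × 4 × 12 = 2,016). Within-subjects
participants cycle through the four languages (one per condition) and
condition order is uniformly randomized.

Two presets ship. `GUESSING` (p ≡ 0.5, σ = 0) exists for chance calibration.
`CUE_PATTERN` encodes the qualitative pattern the paradigm reports — pause
strongest, lengthening strong, baseline and both pitch conditions moderate
and mutually similar, shortening reversed with part-words 2-1 preferentially
accepted — via illustrative cell probabilities (e.g. shortening:
p_word(WORD) = 0.40, p_word(PW21) = 0.80, so correctness on part-words 2-1 is
the designed minimum of the condition by a 0.20 margin, large enough that the
ordering is a property of the model rather than of sampling luck at n ≈ 34).
The magnitudes are free parameters and carry no empirical claim; analyses of
this preset are meaningful only as order relations. σ_subject defaults to
0.5 logits.

## Signal-detection analysis

Per participant-condition cell: 4 signal trials (words) and 8 noise trials
(part-words). Rates of 0 or 1 are replaced by 1/(2N) or 1 − 1/(2N), with N
the trial count of the respective rate (4 for hits, 8 for false alarms) —
the rule is applied per participant, per rate, not to pooled group rates.
d' = z(H_adj) − z(F_adj). Group summaries are per-condition means of
participant d' values with t-based 95% confidence intervals
(mean ± t₀.₉₇₅,ₙ₋₁ · SE); the t-interval is a documented choice — symmetric
and standard for between-participant means. Proportion-correct tables
bootstrap over participants (1,000 seeded resamples by default) with 0.5 as
the chance reference. Mixed-effects models are out of scope by design; the
long-format CSV export provides the exact per-judgment table (participant,
condition, language, order, trial, stimulus type, correctness) needed to fit
them externally.

## Problem sizes and numerical checks

The test suite validates parameter recovery at 10,000 simulated participants
(mean simulated d' against an independent analytic expectation computed by
exact binomial enumeration with Gauss–Hermite integration over the subject
offset, within 4 Monte-Carlo standard errors), chance calibration over 1,000
condition-level replicate intervals at n = 34 (coverage of 0 must be ≥ 90%),
and uniformity of the derangement selector by chi-square over 9,000 draws.
Audio tests render at 16 kHz; the acoustic contract is sample-rate
independent down to the 8 kHz floor.

## What the simulation does and does not show

The synthetic cohort emulates the designs' arithmetic, a plausible
participant heterogeneity structure, and a configurable response pattern. It
does not emulate learning dynamics (exposure duration and memory load have no
effect), item-level difficulty, serial-position or fatigue effects, or any
acoustic influence of the rendered audio on responses — response
probabilities are injected, not derived from the stimuli. Passing tests
therefore certify the stimulus-construction and analysis machinery and the
internal consistency of the response model, not any empirical claim about
human listeners.
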