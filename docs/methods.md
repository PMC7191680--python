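# Methods

This note records the modelling choices behind `clinsts`, their defaults,
and what the synthetic experiments do and do not establish.

## Pre-processing

Sentences are normalized in four steps: NFC unicode normalization plus
lowercasing; punctuation-splitting rewrites ("/" is spaced on both sides,
".-" becomes ". - ", a period squeezed between two *letters* becomes
". " so that decimals like "0.5" survive, and quoting apostrophes are
spaced while contraction apostrophes are kept so the tokenizer can split
"patient's" into `patient` + `'s`); Treebank-style tokenization
(punctuation separation, contraction splitting, digit-internal commas and
colons preserved); and optional removal of stopwords and punctuation-only
tokens. The stopword list is frozen into the package as a data file so
results cannot drift with toolkit versions. Normalization is idempotent,
and tokenization without stop removal preserves every alphanumeric
character in order.

All feature computations run on the pre-processed text: token measures on
the stopword-filtered token sets/sequences, character and sequence
measures on those tokens rejoined with single spaces, and the embedding
backend on the same rejoined string.

## The 14 similarity features

Every feature is symmetric and lies in [0, 1]. Degenerate inputs follow
one convention: empty vs empty compares as identical (1), empty vs
non-empty as maximally dissimilar (0). The field defines several of these
measures as distances or raw alignment scores without a canonical
similarity form, so the normalizations are fixed here:

| measure | definition used |
|---|---|
| Jaccard / Dice / Ochiai | set formulas on the token sets |
| generalized Jaccard | greedy best-first matching of token pairs with Jaro ≥ 0.6 (ties broken lexicographically, each token used once); matched pairs count binarily in the numerator, with a flag to sum Jaro values instead |
| tf-idf cosine | smoothed idf ln((1+N)/(1+df)) + 1, raw tf, L2-normalized vectors; idf is fitted on the deduplicated training-split sentences only |
| q-gram (q = 3, 4) | 1 − Σ\|countₐ(g) − countᵦ(g)\| / (Nₐ + Nᵦ), unpadded sliding windows |
| Levenshtein | 1 − dist/max(\|a\|,\|b\|) (edit distance computed by edlib) |
| bag | 1 − max(\|A−B\|, \|B−A\|)/max(\|a\|,\|b\|) over character multisets |
| Needleman–Wunsch | global alignment with match +1, mismatch −1, linear gap −1 (Biopython `PairwiseAligner`); score affinely mapped by (score + L)/(2L), L = max length, and clipped — self-alignment ↦ 1, all-mismatch ↦ 0 |
| Smith–Waterman | best local alignment under the same scoring, divided by the shorter string's self-score; no positive alignment ↦ 0 |
| embedding cosine | raw cosine clipped below at 0 so the feature shares the [0, 1] range (sentence-embedding cosines are rarely negative in practice) |
| entity similarity | \|Cₓ∩Cᵧ\|/max(\|Cₓ\|,\|Cᵧ\|); both sets empty ↦ 1, consistent with the number feature's neither-side rule |
| number similarity | neither side has numbers ↦ 1; exactly one ↦ 0; both ↦ 1/(1+WMD) over the number words — monotone, 0 ↦ 1, unbounded distance → 0 |

The alignment scoring (+1/−1/−1) is the simplest symmetric scheme; it is
configurable. Number detection covers integer and decimal digit tokens
plus a closed list of spelled-out numbers (one…twenty, the tens, hundred);
digits are converted to words ("24" → "twenty-four") before comparison.

## Embedding backends

The default backend maps each token to a pseudo-random unit vector seeded
by a BLAKE2 digest of the token, and embeds a sentence as the mean of its
token vectors (32 dimensions by default). It is deterministic across
processes and machines, needs no model file, and gives genuinely
distributional behaviour: sentences sharing tokens have correlated
vectors. A sent2vec backend (700-dimensional BioSentVec-style models)
loads lazily from a user-supplied path and fails loudly if the `sent2vec`
package or model file is missing — never a silent fallback. Word vectors
for the Word Mover's Distance come from the hash projection in either
mode, so out-of-vocabulary tokens always embed deterministically. WMD is
solved exactly as a balanced transportation LP (`scipy.optimize.linprog`)
over the bag-of-words marginals with Euclidean ground cost; the 1×1 and
1×m cases use the closed form.

## Concept extraction

Running a full clinical concept extractor is out of scope. Dictionary
mode matches a bundled phrase → CUI lexicon longest-phrase-first over the
token sequence (so "abdominal pain" shadows "pain"); import mode reads
pre-computed annotations (`pair_id TAB side TAB cui,cui`) produced by an
external pipeline such as CLAMP. The bundled lexicon (~40 phrases) is a
development aid, not a clinical resource.

## Encoder network

Input composition is `concat(v₁, v₂, |v₁−v₂|, v₁⊙v₂)` (length 4·dim);
the element-wise product is the standard pairing with the absolute
difference in sentence-pair regressors, and a scalar-dot-product variant
is available behind a flag. Inputs are standardized feature-wise with
training-split statistics; weights use He initialization; the output bias
starts at the training-mean score. Hidden layers (480/240/80) use ReLU;
the output is linear, clipped to [0, 5] at prediction time. Training is
plain SGD at learning rate 10⁻⁴, batch size 32, MSE loss with L2 penalty
(default λ = 10⁻⁴) and inverted dropout 0.5 on hidden layers. Early
stopping monitors validation MSE with 200-epoch patience; the returned
model is the checkpoint with the highest validation Pearson. All
randomness (init, shuffling, dropout) flows from one seeded generator, so
retraining with the same seed, data and backend is bit-reproducible.

The epoch cap defaults to 1000. At the desk scales this package targets
(hundreds of training pairs, 32-dimensional fixture embeddings) the
validation loss is still slowly improving when the cap is reached, so the
cap — not the patience rule — is the effective training length; 1000
epochs trains in about a minute on one CPU and is past the point of
diminishing returns on held-out Pearson.

## Stacking ensemble

Ordinary least squares with intercept over the component models'
validation-set predictions, fitted by `numpy.linalg.lstsq`. Duplicate
identical component columns are dropped (logged) to avoid rank
deficiency; predictions are clipped to [0, 5]. With a single component
equal to the gold scores, the fit recovers slope 1 and intercept 0 to
machine precision.

## Evaluation

Pearson correlation is the headline metric; a constant input raises an
error rather than silently returning 0. Region-wise error assigns each
pair to the unit-width bin containing its *gold* score — [0,1], (1,2],
(2,3], (3,4], (4,5] — and reports per-bin MSE, leaving empty bins absent;
the count-weighted recombination of bin MSEs equals the overall MSE.
Ablation retrains the forest (same seed) without one feature family at a
time, rather than masking at predict time, and reports validation/test
Pearson deltas against the full model. Single-feature screening reports
each raw feature column's correlation with gold, excluding the entity
slots by default (they only apply to concept-bearing sentences);
constant columns report as undefined rather than 0.

## Synthetic generator

The generator emulates the structure of restricted clinical STS corpora.
Each pair samples a similarity band from the default distribution
{0: .08, 1: .12, 2: .20, 3: .34, 4: .20, 5: .06}; sentence A instantiates
a random template from a ~40-sentence bank spanning symptom, medication
and patient-education registers (with number slots and lexicon concept
phrases so the entity and number features are exercised); sentence B is a
band-dependent perturbation — identical (5), synonym swaps (4), swaps
plus token drops or clause reordering (3), clause substitution with
number changes (2), a different same-register template (1), an unrelated
register (0). The gold score is the band plus ±0.25 uniform jitter
clipped to [0, 5], mimicking averaged two-annotator scores. The defaults
put just over half of the gold mass in [2, 4] and make the surface
features strongly predictive (token-overlap vs gold correlation ≈ 0.85 at
n = 500).

What this does *not* emulate: real clinical vocabulary breadth, misspellings
and abbreviation noise, annotator disagreement structure, template reuse
("copy-paste") statistics, or pairs whose semantic similarity diverges
from surface similarity (the case pre-trained biomedical embeddings exist
for). Passing the end-to-end tests therefore demonstrates that the
pipeline is correctly wired and learnable, not that its accuracy carries
over to real notes; on synthetic data the hash-projection cosine behaves
like another surface measure.

## Experiment scales

The packaged experiments use 950 generated pairs — 600 train / 150
validation / 200 test, with the labeled 750 split 4:1 by seeded shuffle —
the forest with 500 trees, and the encoder at its 1000-epoch default;
the whole cycle runs in about a minute on one CPU.

## Known limitations

- The bundled lexicon and synonym table are small; entity and number
  features on real notes require the import-mode annotations and a real
  embedding model.
- The encoder's (v₁, v₂) concatenation makes its input order-sensitive
  even though |v₁−v₂| and v₁⊙v₂ are symmetric; the engineered feature set
  is fully symmetric under sentence swap. This asymmetry is inherited
  from the architecture, asserted in tests, and documented rather than
  hidden.
- Generalized Jaccard uses greedy best-first matching, a deterministic
  approximation to optimal assignment; with Jaro threshold 1 it reduces
  exactly to plain Jaccard.
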