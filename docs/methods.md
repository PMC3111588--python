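# Methods

## Problem setting and model

`mmbdeid` removes author-identifying tokens from medical message board
(MMB) posts. Identifiers fall in two classes with different detection
regimes:

* **Structured identifiers** (e-mail, phone, URL) have rigid surface
  syntax and are matched by regular expressions before tokenization, so
  their internals never reach the classifier. Precedence on overlapping
  matches is EMAIL > URL > PHONE, and the phone pattern only runs on
  text not already claimed — digit runs inside URLs are not phone
  numbers. The e-mail pattern's tail is `(\.\w+)*` (literal dot): an
  unescaped dot there would swallow arbitrary characters after the
  host, which is not what an e-mail address looks like.

* **Names** (proper names and usernames) have no rigid syntax in forum
  text. They are modeled with a linear-chain conditional random field
  over the token sequence of each message, with label set
  {PROPER_NAME, USERNAME, OTHER}. No BIO prefixes: forum name mentions
  are overwhelmingly single tokens, and token-level tagging is what the
  evaluation measures. The CRF is the right model family here because
  name evidence is contextual (an honorific or greeting word two tokens
  away matters) and the output decision is per-token probabilistic —
  the recall-oriented threshold below needs calibrated marginals, not
  just a Viterbi path.

Tokenization splits at whitespace and at *every* punctuation character
(each becomes a one-character token). This mangles contractions
("don't" → `don ' t`) but is the only rule that behaves predictably on
forum text, where punctuation is used creatively; names broken by
stray punctuation are recovered by the fuzzy lexicon features.

## Feature set

Per token: identity and lower-cased identity, length, case class
(exactly one of lower/upper/capitalized/mixed for alphabetic tokens),
2- and 3-character prefixes/suffixes, edge distances (raw, capped at 5,
plus within-1/within-2 edge flags), exact membership in eight word
lists, fuzzy membership (edit distance ≤ 1 and ≤ 2) in each list,
tf-idf rank buckets under two corpus segmentations, and
paragraph-border rank buckets. Every token also receives the full
non-context feature set of its two left and two right neighbors under
an offset prefix; context is simply absent past message edges.
Punctuation tokens carry features and serve as context but are excluded
from all corpus statistics and from evaluation counts, and the pipeline
never lets a lone punctuation mark keep a name tag.

**Word lists.** proper names, common words, stop words, medical terms,
drug names, honorifics, all usernames of the corpus (from the author
field), and per-thread username variants. Variants are derived by
stripping digits, splitting at non-alphanumeric delimiters and
camel-case boundaries, and greedily cutting the digit-stripped handle at
known name/word boundaries ("kaygirl99" → kaygirl, kay, girl); derived
variants under 3 characters are suppressed — they carry almost no
identifying power and would flood fuzzy matching. The bundled lists are
small synthetic stand-ins with the same roles; production deployments
drop in real gazetteers via `load_lexicons` paths.

**Edit distance.** Damerau–Levenshtein in the optimal-string-alignment
variant: insertions, deletions, substitutions, adjacent transpositions,
no substring edited twice. That is the natural reading of the four
listed operations, and transpositions are the dominant typo class in
fast-typed text. Fuzzy membership is inclusive of exact members (so it
is monotone in the distance bound); both exact and fuzzy flags are
emitted and the classifier can use their difference. Queries run
against a deletion-neighborhood index (any two strings within k edits
share a member of each other's k-deletion neighborhoods; candidates are
confirmed with the exact distance). The index has a contract identical
to a naive scan — property-tested against one — but answers in
near-constant time, which matters because fuzzy membership is queried
for every token against eight lists.

**tf-idf.** `score(i, j) = (count(i,j)/√|j|) · ln(N/nᵢ)` over two
segmentations: all messages of a board as one document, and all posts
of one author as one document. Names are document-specific under both;
filler is not. The idf logarithm is natural — the base only rescales
scores, and only ranks are consumed (bucket flags: top-10 and top-1% of
a document's distinct tokens). Tokens are lower-cased and punctuation
dropped before counting; rank ties break lexicographically so the
feature stream is deterministic.

**Paragraph borders.** A paragraph is a maximal run of non-blank lines
within a body; a border occurrence is a token within k = 3 tokens of a
paragraph's first or last token (greetings and sign-offs occupy short
opening/closing lines). Token score = `(border/total) · ln(total)`,
corpus-wide; bucket flags are top-5 and top-10%. The log damping keeps
one-off tokens (always trivially at a border) from outranking genuinely
recurrent sign-off names.

## CRF implementation and training

The CRF is implemented in the package (numpy/scipy): state weights over
string-valued binary features, a 3×3 transition matrix, and start/end
bonuses. Training minimizes the L2-penalized negative conditional
log-likelihood with L-BFGS; gradients come from forward–backward run in
log space, batched over all sequences at once (padded positions carry
the previous value forward, so each sequence's terminal vector is
always in the last slot). Zero initialization and no sampling make
training bit-deterministic for fixed data; the `seed` in the config is
plumbed for completeness but nothing consumes randomness. Marginals are
normalized per token (they sum to 1 up to 1e-9 and are renormalized
once at the end). Forward–backward is verified in tests against
explicit enumeration of all label paths on short sequences.

Defaults: `c2 = 0.1` (L2 strength; the synthetic task is easy and
mild shrinkage suffices), `max_iter = 120` (L-BFGS converges on the
reference corpus well before this), `min_feature_count = 1` (the
feature space at reference scale, ~30k features, needs no pruning).
True flags are emitted as bare feature strings, False flags omitted —
with the always-on `bias` feature this is informationally equivalent
for a log-linear model and halves the design matrix.

## Thresholding and post-processing

A token is tagged as a name when
`P(PROPER_NAME) + P(USERNAME) > name_threshold` (strict inequality),
taking the more likely name label, ties to PROPER_NAME (an arbitrary
but deterministic choice; the evaluation counts either name label as a
hit, so the tie-break is cosmetic). The cumulative formulation is
deliberate: the two name classes are confusable with each other but
that confusion is irrelevant to de-identification. The default
threshold 0.05 trades precision for recall; the tagged set is provably
monotone in the threshold, so recall never decreases as the threshold
drops. A final pass untags exact (case-insensitive) drug-lexicon
members: drug mentions are the tokens researchers most need kept.
Fuzzy drug matching is deliberately absent — drug nicknames ("doxy")
are genuinely ambiguous with user nicknames, and untagging them would
leak names.

Scrubbing replaces identifier spans and name-tagged tokens with
bracketed class placeholders, preserving all other bytes. Placeholder
class words flanked by brackets are never re-replaced, making scrubbing
idempotent.

## Synthetic corpus generator

The generator emulates the structural regularities the features
exploit: boards → threads → messages; 8 board-local users per board
with handles composed from name/word pool pieces plus optional digits
(so variant derivation can invert them); every thread has at least two
posting voices; messages open with probability `p_greeting = 0.7` by
addressing another poster by a handle fragment, close with probability
`p_signoff = 0.6` with the author's first name, mention other
participants mid-text with probability 0.15, and embed e-mails, phones
and URLs at low rates (0.05/0.05/0.08). Planted names receive one
random character edit with probability `p_typo = 0.1`. Filler is drawn
from the common-word pool with Zipf weights, so names are
document-specific while filler is corpus-wide — the property the
tf-idf features depend on. The reference conditions are 5 boards × 10
threads × 20 messages = 1000 messages, split 4 boards / 1 board so
every test-set username is unseen in training. All randomness flows
from one integer seed; identical configs yield byte-identical corpora.

What the generator does **not** emulate: real medical discourse, quoted
replies, handles colliding with in-message common words used as filler,
acronym nicknames, multilingual text, or the long-tail spelling chaos
of real forums. Consequently the near-perfect held-out metrics on
synthetic data demonstrate that the pipeline's machinery — feature
extraction, training, thresholding, scrubbing — is correct and that the
intended signals are learnable from the intended features; they say
nothing quantitative about performance on real boards, where published
results for this class of system sit near 94% recall at ~61% precision.

## Numerical and degenerate-input choices

* Zero-denominator metrics (e.g. precision with nothing tagged) report
  1.0 with the metric named in `zero_denominator`, rather than raising:
  all-negative fixtures are routine in testing.
* Inter-coder agreement returns percentages rounded half-even to one
  decimal; from the published counts (83, 82, 81) this gives
  (97.6, 98.8), 81/82 being 98.78%.
* Empty messages produce empty token, feature and label streams
  throughout; an empty document set for tf-idf is an error.
* Unknown features at prediction time are ignored; a model predicts
  with exactly the vocabulary it was trained with, and a
  feature-schema version embedded in the model artifact guards against
  tagging with features from a different pipeline revision.
* Lenient re-coding automates only the mechanical rule (token length
  ≤ 3, substring of a participant username strictly longer than twice
  the token); acronym/nickname judgments require human flags and are
  accepted as explicit (message, token) pairs.
* Error-taxonomy buckets are mechanical proxies (list membership,
  length, edit distance to participant handles) applied in a fixed
  precedence order; they approximate, not reproduce, human error
  categorization.

## Known limitations

* The tokenizer's aggressive punctuation splitting inflates token
  counts and splits contractions; evaluation excludes punctuation
  tokens, so metrics are unaffected, but downstream consumers of token
  indices must use this package's tokenizer (annotation files record a
  tokenizer version for exactly this reason).
* The URL pattern is heuristic (scheme or leading `www.`); bare-domain
  URLs ("example.com") pass through. It is configurable per corpus.
* Postal addresses, locations and institutions are not modeled; any
  removal of them is a by-product of the name classifier.
* Training assumes per-message label streams aligned to this package's
  tokenization; there is no span-offset import path for third-party
  annotations.
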