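# mmbdeid

De-identification of medical message board (MMB) posts.

Public forum posts by patients are a rich source of data on treatment
experiences, but they are full of identifying text: e-mail addresses,
phone numbers, URLs, and — much harder — proper names and usernames.
Forum text defeats de-identifiers built for clinical records or
newswire: it is riddled with typos, users go by invented handles
("kaygirl99") and address each other by fragments of those handles
("kay"), and many handles collide with ordinary words. `mmbdeid`
implements a de-identification pipeline designed for exactly this
medium, for researchers who need to scrub forum corpora before analysis
or sharing.

## Method

The pipeline has three stages:

1. **Pre-processing.** Structured identifiers are found by regular
   expression — e-mail `[\w.]+@\w+(\.\w+)*`, phone
   `(\d\d\d[-._ ]?)+\d\d\d\d`, and a scheme-or-`www` URL pattern — and
   excised; the remaining text is split into tokens at whitespace and at
   every punctuation mark.

2. **Name classification.** A linear-chain conditional random field
   assigns each token marginal probabilities over
   {PROPER_NAME, USERNAME, OTHER}. Its features combine surface cues
   (token identity, case class, 2/3-character affixes, distance from the
   message edges), word-list membership — eight lexicons including
   usernames of the board and automatically derived username *variants*
   (digits stripped, delimiter/camel-case/known-word splits), with fuzzy
   membership within Damerau–Levenshtein distance 1–2 to catch
   misspellings — and board-structure statistics: tf-idf rank of the
   token when all messages of a board, or all posts of one author, are
   pooled as documents (`score = (count/√|doc|) · ln(N/nᵢ)`), and the
   corpus-wide likelihood of appearing near a paragraph border, where
   greetings and sign-offs live. Each token also carries its two left
   and two right neighbors' features.

3. **Post-processing.** Any token whose *cumulative* name probability
   `P(PROPER_NAME) + P(USERNAME)` exceeds a threshold (default 0.05 —
   chosen for recall: a missed name is worse than an over-scrubbed word)
   is tagged with the more likely name label; tokens that are exact
   members of the drug lexicon are untagged; every identifier is
   replaced by a placeholder (`[NAME]`, `[USERNAME]`, `[EMAIL]`,
   `[PHONE]`, `[URL]`).

Evaluation reports precision, recall, F-score and specificity over
non-punctuation tokens, with either name label counting as a hit, plus
a lenient mode that re-codes gold names carrying negligible identifying
power (e.g. a ≤ 3-character substring of a much longer username).

Real forum corpora cannot be redistributed, so the package ships a
synthetic-corpus generator (`mmbdeid.synthetic_data`) that reproduces
the structure the features exploit — boards, threads, board-local users,
greetings by username variant, first-name sign-offs, typos, embedded
e-mails/phones/URLs — with gold labels for every planted identifier.

## Worked example

```python
from mmbdeid import GeneratorConfig, generate_corpus, split_corpus, train_deidentifier
from mmbdeid.tagger import TaggerConfig

corpus, gold = generate_corpus(GeneratorConfig(seed=1))          # 1000 messages
train_c, train_g, test_c, test_g = split_corpus(corpus, gold, 0.8, seed=1)
deid = train_deidentifier(train_c, train_g, TaggerConfig())

print(deid.evaluate(test_c, test_g).summary())
```

Training uses the 800 messages of four boards; evaluation runs on the
200 messages of a held-out board whose usernames never occur in
training. The run prints:

```
mode=strict TP=353 FP=0 FN=0 TN=4619
precision=1.0000 recall=1.0000 f_score=1.0000 specificity=1.0000
tagging_error_rate=0.0000
```

i.e. all 353 planted name tokens on the unseen board were recovered and
none of the 4619 ordinary tokens were falsely scrubbed. (Real forum text
is far harder than the generator's output; see `docs/methods.md` for
what this does and does not demonstrate.) Scrubbing a test message:

```
Jeanneread , hi !                      [USERNAME] , hi !

felt everything about alone . able     felt everything about alone . able
after away about jeanne . fear ...     after away about [NAME] . fear ...

robin                                  [NAME]
```

The same pipeline is scriptable from the shell:

```sh
mmbdeid synth --out-corpus corpus.jsonl --out-gold gold.tsv --seed 1
mmbdeid train --corpus corpus.jsonl --gold gold.tsv --model model.npz
mmbdeid scrub --corpus corpus.jsonl --model model.npz --out clean.jsonl
mmbdeid eval  --corpus corpus.jsonl --gold gold.tsv --model model.npz
```

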