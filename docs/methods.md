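# Methods

## Problem and model

The package analyzes a keyword-collected tweet stream about an inherited
cancer-risk condition (Lynch syndrome / HNPCC) to ask three questions: what
topics are discussed, how promotional information (link-carrying tweets
from organizations, news media and advocates) relates to laypeople's own
discussions, and what scheduled awareness events (Colon Cancer Awareness
Month in March, Lynch Syndrome Awareness Day on March 22) do to volume and
attitude. The analysis is descriptive: correlation of monthly volumes, not
causal inference.

### Normalization

Raw text is reduced to whitespace tokens with four substitutions:
`#Phrase` → the token pair `<hashtag>` + lowercased phrase (kept whole; no
camel-case splitting, matching the convention that the hashtag phrase
itself carries topic signal), `@name` → `<user>`, `http(s)://…` → `<url>`,
emoji runs → `<emoji>`; everything else is lowercased. Patterns are the
conventional GloVe-style choices: `#`/`@` followed by word characters, a
case-insensitive URL scheme prefix, and the standard emoji Unicode blocks.
Substitution is idempotent because placeholders contain no trigger
characters. For topic modeling a second pass removes placeholders, stop
words (a bundled ~140-word English list), tokens shorter than two
characters, and applies a pluggable lemma mapping whose default is the
identity — no third-party lexicon is required for tests to run.

### Classification

Two cascading rules partition every tweet: token-exact "willie"/"willy" ⇒
irrelevant (word-level matching avoids firing inside longer strings);
then `<url>` present ⇒ promotional, absent ⇒ layperson. Running the rules
on normalized tokens makes the stages compositional with preprocessing.
Evaluation uses one-vs-rest precision/recall/F per class aggregated with
gold-support weights, where weighted F is the support-weighted mean of
per-class F (the convention of common metrics libraries), and Cohen's
κ = (p_o − p_e)/(1 − p_e) with chance agreement from the two annotators'
marginals.

### Topic model

LDA is fitted by collapsed Gibbs sampling with the standard conditional
p(z_i = k) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ). Defaults are α = 50/K,
β = 0.1 and 1000 sweeps; estimates are Dirichlet-smoothed posterior means
from the final sweep's counts (no sample averaging — simpler and exactly
reproducible; averaging can be layered on by the caller). All randomness,
including the initial assignment, flows from one seed set inside the
sampling kernel, so a fit is bit-reproducible. The kernel is compiled with
numba; the per-sweep topic-count trace can be retained for diagnostics.

Three diagnostics guide the choice of K, each computed on a model refitted
from scratch per candidate (seed offset by K) for comparability:

* **symmetric KL factor check** (lower better): divergence between the
  normalized singular values of the topic-word matrix and the
  length-weighted, normalized topic proportions of the document-topic
  matrix;
* **mean inter-topic cosine** (lower better): average pairwise cosine of
  topic-word rows;
* **mean inter-topic Jensen–Shannon divergence** (higher better), natural
  log, bounded by ln 2.

Per-tweet attribution thresholds the document-topic row at a cutoff
(default 0.1 — consistent with published examples where at most three
topics per tweet are reported and the smallest printed probability is
.118); the primary topic is the argmax, ties broken toward the lower
index, and tweets where nothing clears the cutoff remain unassigned.
Topic labels and many-to-one merges (e.g. "awareness" + "awareness event")
are a user-supplied map, since labeling is a human step.

Before LDA the pipeline driver also stops out the collection-keyword
tokens ("lynch", "syndrome", "lynchsyndrome"): every collected tweet
contains them by construction, so they carry no discriminative signal and
would only blur the topic-word rows.

### Sentiment

The sentiment stage accepts any callable from normalized tweet to
{positive, negative, neutral}; the reference implementation sums lexicon
polarities (+1/−1 per word, two-column CSV) and takes the sign, with ties
and no-hit tweets neutral. Negation handling is intentionally absent — it
is orthogonal to the pipeline contract. Groups of tweets are summarized by
(n_pos − n_neg)/n_total in [−1, 1]; an empty group is *missing*, not 0.
Table percentages are rounded half-up to two decimals, the convention that
reproduces the published cells from their printed counts.

### Trends

The monthly panel counts tweets per (UTC calendar month × class × primary
topic × polarity). Volumes use the primary topic only, matching mutually
exclusive per-topic bars; counting every above-cutoff topic is available
as an alternative reading but is not the default. Pearson r is computed
from the definition, with the two-sided p-value from
t = r√((n−2)/(1−r²)) on n−2 degrees of freedom; constant series yield
missing values rather than numbers. Partial boundary months are included
as-is. P-values render to three decimals with "<.001" below 0.001.

## Synthetic corpus generator

The generator emulates exactly the statistical structure the analysis
assumes: a planted K×V topic-word matrix (rows ~ Dirichlet(topic_word_conc)),
per-tweet topic mixtures (~ Dirichlet(doc_topic_conc)), Poisson tweet
lengths truncated to ≥ 3 tokens (LDA degenerates on empty documents),
synthetic vocabulary strings "w0001"… that cannot collide with
placeholders, keywords or lexicon words, class-conditional URL decoration,
distractor keywords in irrelevant tweets, planted layperson polarity
realized by injecting a matching lexicon word, and uniform monthly volume
except one event month scaled by a multiplier. One RNG stream seeded once
drives the draw in a documented fixed order, so generation is
bit-reproducible within this implementation.

Defaults encode the study conditions: eleven months 2016-10 … 2017-08 with
the event in 2017-03 (multiplier 3), layperson URL rate 0.12 (88% of lay
discussions carry no link), distractor rate 0.96 among irrelevant tweets,
layperson polarity mix (0.184, 0.035, 0.781) matching the observed overall
sentiment distribution, and class mix (0.186, 0.628, 0.186): the
irrelevant and layperson shares observed in the collected English tweets,
with promotional taking the remainder (the published counts are not fully
self-consistent, so the generator uses this consistent resolution).
Tweet length (mean 12), vocabulary size (200 default; 60–80 in the
recovery experiments) and the Dirichlet concentrations are free
parameters chosen as realistic for short social-media posts; the
promotional URL rate is 0.95 (promotional tweets "usually" reference a
source, not always).

What the generator does **not** emulate: real Twitter language, user
networks, retweet cascades, character limits, non-English text, or
near-duplicate spam. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance of the
rules or lexicon on real tweets.

## Numerical and design choices

* Gibbs estimates come from the final state; chains for different K are
  independent (no warm starts) so diagnostics are comparable.
* KL/JSD computations clip probabilities at 1e-12; phi/theta rows are
  row-stochastic to 1e-9 by construction.
* Exact probability ties: topic assignment prefers the lower topic index;
  top-word export breaks ties lexicographically; volume-ranking ties are
  lexicographic.
* Percentages round half-up (not banker's rounding) to match printed
  tables; internal values are unrounded.
* The weighted-F convention is the support-weighted mean of per-class F,
  not the F of weighted P and R.
* Problem sizes in the test and acceptance experiments (e.g. D ≈ 500,
  V = 60–80, 150–200 sweeps, 10 seeds for recovery and K-selection) were
  chosen as the smallest settings at which the planted-recovery behavior
  is stable and clearly separated from failure, keeping the full suite
  fast enough to run routinely.

## Known limitations

* The rule-based classifier's published performance (weighted F ≈ .94/.87
  on a 1000-tweet gold standard) cannot be reproduced without the original
  corpus; the package reproduces the rules and the evaluation machinery.
* The lexicon baseline is a stand-in for the study's CNN sentiment
  classifier (out of scope by design); on real text its accuracy depends
  entirely on the supplied lexicon.
* Topic-count diagnostics are heuristics and, as in the original analysis,
  may fail to agree or converge on real corpora; human review of topic
  quality remains necessary.
* The manual steps of the original workflow — topic labeling/merging and
  the 50-tweet cutoff calibration loop — are supported via configuration
  (label map, cutoff parameter) but not automated.
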