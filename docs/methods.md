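# Methods

This note records the models, parameter choices and numerical conventions
behind `rxcircles`, and what the synthetic-data tests do and do not establish.

## Social-circle discovery

**Model.** A social circle around an index user is a dense set of mutually
aware users, found by local community search on the directed follow graph: the
global graph never needs to be known, only the out-neighbourhoods of current
members. The circle starts as `{index}` (step 0) and grows one member per
iteration until a target size is reached. Candidates are exactly the users
followed by at least one member (candidate generation uses out-edges only;
scoring uses both directions). A candidate's score is the minimum of its
discounted follow-count into the circle and the discounted follow-count from
the circle:

    score(n) = min( Σ_c e(n,c)·δ(s(c)),  Σ_c e(c,n)·δ(s(c)) )

The `min` demands *mutual* awareness — a user followed by many members but
following none of them (a celebrity) scores 0, as does a pure follower.

**Discount.** δ damps the pull of late additions so the circle stays anchored
to the index user. The exact functional form is a policy choice isolated
behind `DiscountPolicy`; the default is exponential, `δ(s) = γ^s` with
`γ = 0.95`, chosen because it is smooth, monotone, and reduces to the plain
count definition at `γ = 1`. Any alternative non-increasing policy can be
swapped in without touching the algorithm.

**Pruning.** After additions 5, 10, 15, … the non-index member with the lowest
score — computed by the same formula against the rest of the circle, with the
same discounts — is removed. The index user is exempt. Step labels are
addition indices: they are never reassigned, pruning does not decrement the
counter, and a pruned user re-added later receives a new, later step.

**Determinism and termination.** Ties (both argmax additions and prune
victims) break toward the lexicographically smallest user id, making runs
reproducible. Net growth is +4 per 5 additions while candidates exist; a
safety cap of `50 × target_size` additions guards pathological re-addition
cycles. If the candidate pool empties first, the partial circle is returned
with `stop_reason="exhausted"` (a warning, not an error — small graphs are a
first-class use case).

**Growth/prune interleaving.** The loop stops the moment the circle reaches
the target size; a prune scheduled for that same addition index does not fire.
This convention is applied identically in the package and in the brute-force
oracle used by the tests.

## Keyword categorization

Matching is case-insensitive over tokens split on non-alphanumeric boundaries.
A plain keyword must equal a whole token (multi-word keywords: a contiguous
token run), so "overdose" does not match "overdosing" and "two" does not match
"network"; a trailing `*` matches any token beginning with the stem. These two
rules are the whole matching dialect — no stemming, spelling correction or
learned classification, favouring precision over recall (counts are lower
bounds on discussion).

Behavior categories are only assessed on posts that already matched a drug
keyword. Three keyword gates apply:

* the co-ingestion keywords "xanax"/"adderall" are inert for posts whose
  *only* drug category is Xanax resp. Adderall (a drug is not its own
  co-ingestant), but stay active when another drug category is present — a
  post mentioning both xanax and adderall is co-ingestion via the other
  drug's name;
* "test", "final", "study", "studying" fire only for Adderall posts;
* "skinny" fires only for Stimulants posts.

Duplicate keywords within a category's printed list are deduplicated with no
semantic effect. Mentions are `@handle` tokens (1–15 chars of `[A-Za-z0-9_]`)
whose `@` is not preceded by an alphanumeric, so e-mail addresses do not
count; "RT @user" retweet prefixes do. Retweets are not deduplicated: every
record in a corpus is counted.

## Circle statistics

* **Topic vector**: fraction of an entity's drug posts matching each of the 7
  categories; multi-category posts count toward each, so entries can sum past
  1. Undefined (flagged, NaN) at zero drug posts.
* **Topic correlation**: Pearson r between the index user's vector (all their
  drug posts) and the *pooled* posts of all other members treated as one
  pseudo-entity — pooling, not averaging member vectors, weights active
  members more, matching the aggregate-tweets convention. With only 7 points
  the per-circle p-values are low-powered and flagged as such.
* **Abuse level**: number of distinct behavior categories across a user's
  posts — a severity surrogate (4 categories ranks above 1), monotone in the
  user's posts.
* **Aggregation**: column means use sample SD (n−1). The topic-correlation
  column is averaged via Fisher's z (`tanh(mean(atanh r))`); undefined
  correlations are excluded with a reported count; r = ±1 is clamped to
  ±(1−10⁻⁷) with a warning. Engagement-vs-abuse correlations are Pearson r
  between the mention-user and abuse-user counts across circles (counts equal
  percentages at the default circle size of 100, and r is scale-invariant
  anyway).
* **Mention posts** count any extracted mention, including targets outside
  the circle (a `internal_only` switch restricts interaction graphs to
  members).

The packaged 25-circle summary table is transcribed at full printed precision,
and `verify_fixture` recomputes every aggregate from the raw rows. Tolerances
are: exact for integer sums/extremes, 0.005 for 2-decimal quantities, and half
a printed unit (0.05) for 1-decimal quantities — except the mention-user and
abuse≥1 SDs, where the published table truncates rather than rounds (21.269 →
21.2, 18.882 → 18.8) and one printed unit (0.1) is used. The published
abstract reports the population SD of the poster column (24.3) while the table
prints the sample SD (24.8); the package computes sample SD.

## Synthetic worlds

**What is emulated.** A directed stochastic block model: edge `x→y` appears
with the intra-block probability when x and y share a block (default 0.6) and
the inter-block probability otherwise (default 0.02) — dense, mutually aware
planted circles in a sparse background. Each user posts a Poisson number of
posts (default mean 60); each post is a drug post with the block's probability
(default 0.25); drug posts draw one category from the block's 7-way mixture
(the default world gives each block a rotating dominant drug with weight 0.6,
so an index user and their block discuss similar drugs), independently inject
each of the 8 behavior keywords with block-level probabilities (default 0.008
each), and @-mention a uniformly chosen same-block user with the block's
mention probability (default 0.08). Defaults were set once so that a
100-member planted circle lands in the published table's ranges (most members
posting drug terms, roughly 60% of drug users matching ≥1 abuse category,
roughly 70% of drug users mentioning someone).

**Text synthesis.** Post text is neutral filler plus verbatim lexicon
keywords. Injection keywords are chosen to be unambiguous (Painkillers injects
"oxycontin", never "painkiller", which is also a co-ingestion keyword;
Stimulants injects "ritalin", not "concerta"), and a collision linter
re-categorizes every generated post at generation time, failing loudly if the
text matches anything beyond its intended categories — so the ledger is
faithful by construction, not by hope.

**Coupling.** Two latent uniforms per block drive heterogeneity: the abuse
latent scales all behavior-injection probabilities and the mention latent
scales the mention probability, both linearly over `[1−spread, 1+spread]`
(default spread 0.6). A `coupling ∈ [0,1]` mixes the mention latent toward the
abuse latent: independent at 0, identical at 1. `sweep_coupling` simulates
replicate worlds per coupling level, summarizes each *planted* block as a
circle and reports the across-block engagement-abuse Pearson r with a t-based
CI on the z scale. Planted blocks (not re-discovered circles) are used because
the coupling sweep measures a corpus property and discovery recovery is
validated separately; `predicted_engagement_abuse_r` gives a closed-form
approximation (Poisson drug counts, binomial block noise) that tracks the
Monte-Carlo estimate. The sweep's default world uses lower per-behavior and
mention rates than the paper-scale default so block-level fractions sit
mid-range — correlation is unmeasurable once every block saturates near 100%.

**Determinism.** One integer seed; per-user substreams are derived from
(seed, stream-id, user index), so adding users to a config does not perturb
the posts of existing ones, and identical configs give byte-identical corpora.

**What a green test does not establish.** The generator does not model
realistic language (only keyword presence), misspellings, temporal dynamics,
bots, hub users or heavy-tailed degree distributions; real follow graphs are
not block models. Green planted-recovery and coupling tests establish the
pipeline's correctness and calibration on its stated assumptions, not
performance on real platform data.

## Known limitations

* Keyword matching measures discussion, not behavior; precision-oriented
  lexicons undercount (no misspellings/slang), and matches can be
  non-abusive uses of a word.
* Circle discovery assumes the follow neighbourhooods of members are fully
  observed; private or deleted accounts violate this silently.
* The 10–99 drug-post index-user filter plus the ≥1-abuse-match requirement is
  a deterministic stand-in for the original manual screening of index users;
  it does not replicate human judgment.
* Per-circle topic correlations over 7 categories have ~5 degrees of freedom;
  treat their p-values as descriptive.
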