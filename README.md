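# rxcircles

Social-circle discovery and lexicon-based content analysis for studying
prescription-drug-abuse discussion in microblog (Twitter-style) corpora.

## The problem

Prescription-drug abuse is strongly shaped by social context: people learn,
normalize and source drugs through their peers. Public microblog platforms
expose both the *conversation* (posts) and the *relationships* (a directed
"follow" graph), so one can ask whether users who show signs of abuse are
embedded in circles that discuss and reinforce the same behavior. `rxcircles`
implements that observational pipeline for researchers in digital epidemiology
/ infodemiology:

1. **Local social-circle discovery** on a directed follow graph. Starting from
   a single index user, the circle `SC` is grown to a target size (default
   100). At each step, every user followed by a current member is a candidate,
   and candidate `n` is scored

   `score(n) = min( Σ_{c∈SC} e(n,c)·δ(s(c)),  Σ_{c∈SC} e(c,n)·δ(s(c)) )`

   where `e(x,y)` indicates a follow edge, `s(c)` is the step at which member
   `c` joined, and `δ(s) = γ^s` (default `γ = 0.95`) discounts connections to
   late additions so the circle cannot drift away from the index user. Every 5
   additions the lowest-scoring member is pruned. With `γ = 1` the score is the
   plain min(#members followed, #members following) — the undiscounted
   definition. Unlike an ego network, the circle can contain users with no
   direct tie to the index.

2. **Keyword categorization** of posts into 7 prescription-drug categories
   (Adderall, Xanax, Klonopin, Valium, Painkillers, Depressants, Stimulants)
   and — for drug posts only — 8 risk/abusive-behavior categories (larger
   doses/overdose, co-ingestion, more frequent doses, alternative
   motives/dependence, alternative routes of admission, legitimacy of
   obtaining, trading/selling, seeking). Matching is case-insensitive and
   token-based with a trailing-`*` wildcard; a drug's own name never counts as
   its co-ingestant, and a few study keywords ("test", "skinny", …) are gated
   to specific drugs. `@handle` mentions are extracted as the engagement
   signal.

3. **Circle statistics.** Per circle: drug-post and poster counts, mention
   (directed) posts and posters, each member's *abuse level* (number of
   distinct behavior categories across their posts), and the Pearson
   correlation between the index user's 7-component drug *topic vector* and
   that of the pooled rest of the circle. Across circles: column means and
   sample SDs, the mean topic correlation via Fisher's z transform
   (`tanh(mean(atanh r_i))`), and the engagement-vs-abuse correlations.
   Drug-mention interaction graphs (directed, weighted by number of drug posts
   from one user mentioning another) are exported as GraphML.

4. **Synthetic worlds.** A directed stochastic-block-model generator with a
   ground-truth ledger plants dense "circles", block-dependent drug-topic
   mixtures, abuse-keyword rates and mention rates (optionally coupled), so
   every stage is testable end to end without any platform data.

## Worked example

```python
from rxcircles import DiscountPolicy, default_config, discover_circle, simulate

config = default_config(seed=11, n_blocks=3, block_size=40, tweet_rate=0.0)
graph, _, ledger = simulate(config)
circle = discover_circle(graph, ledger.blocks[0][0], target_size=40,
                         policy=DiscountPolicy(gamma=0.95))
planted = set(ledger.blocks[0])
print(len(circle), circle.stop_reason,
      len(circle.member_ids & planted) / len(circle.member_ids | planted))
```

prints

```
40 target_reached 1.0
```

— the circle reached its target size and recovered the planted 40-user block
exactly (Jaccard 1.0) from the seed user alone.

Recomputing the published across-circle aggregates from the packaged 25-circle
summary table (`python examples/published_table_aggregates.py`) prints, e.g.:

```
sum_drug_tweets                      7290.0000       7290
mean_drug_tweet_users                  53.9600      53.96
mean_mention_users                     37.7600       37.8
fisher_mean_topic_correlation           0.7318       0.73
r_engagement_abuse_ge1                  0.8464       0.85
r_engagement_abuse_ge2                  0.8106       0.81
all within printed precision: True
```

meaning: on average ~54 of each 100-member circle posted a drug term at least
once, ~38 directed such a post at another user, index users and their circles
discuss similar drugs (Fisher-z mean topic correlation 0.73), and circles with
more drug-related interaction contain more members matching abuse categories
(r = 0.85 for ≥1 category, 0.81 for ≥2).

The other `examples/` scripts each exercise one capability: categorizing
posts, running the full pipeline (`analyze_circles.py`), and sweeping the
generator's engagement–abuse coupling (`coupling_sweep.py`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, all published across-circle aggregates from the
packaged summary table and then runs the full synthetic pipeline (simulate →
categorize → select index users → discover circles → analyze) with the given
seed, printing each stage's record counts and writing its JSON result to
`--out`.

## Scope

The package analyzes corpora it is given (or simulates); it contains no
platform API client, and nothing here supports conclusions about any real
person's behavior — keyword matches measure *discussion*, not consumption.
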