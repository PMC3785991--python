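"""Categorize a handful of posts into drug and risk-behavior categories.

Each post is checked against the 7-drug keyword lexicon; posts that mention a
drug are further checked against the 8 behavior lexicons (with the per-drug
keyword restrictions), and @-mentions are extracted.
"""

from rxcircles import Tweet, categorize_corpus

posts = [
    Tweet("1", "alice", "Seriously. Need adderall. Will pay $$$. Help me."),
    Tweet("2", "bob", "@alice Haha! For me it's a nice ritalin/sangria combo :)"),
    Tweet("3", "carol", "xanax then more xanax"),
    Tweet("4", "dave", "valium before my test"),
    Tweet("5", "erin", "good morning everyone"),
]

for ct in categorize_corpus(posts):
    print(
        f"{ct.tweet.author_id:>6}: drugs={sorted(ct.drug_categories) or '-'} "
        f"behaviors={sorted(ct.abuse_categories) or '-'} mentions={list(ct.mentions) or '-'}"
    )

print(
    "\nEach line shows which drug categories a post matched, which risk "
    "behaviors co-occurred (only assessed on drug posts; note the post about "
    "only xanax does not count as co-ingestion, and 'test' is Adderall-gated), "
    "and any @-mentioned users."
)
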