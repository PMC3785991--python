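"""Recompute the published across-circle aggregates from the packaged table.

The package ships a transcription of the published 25-circle summary table;
this script recomputes every aggregate (sums, means, SDs, the Fisher-z mean of
the topic correlations, and the engagement-vs-abuse correlations) from the raw
rows and prints them next to the published values.
"""

from rxcircles import verify_fixture

report = verify_fixture()
print(f"{'quantity':35s} {'computed':>10s} {'published':>10s}")
for check in report.checks:
    print(f"{check.name:35s} {check.computed:10.4f} {check.expected:10.4g}")
print(f"\nall within printed precision: {report.all_passed}")

print(
    "\nThe engagement-abuse correlations (r about 0.85 and 0.81) say that "
    "circles whose members @-mention each other about drugs more also contain "
    "more members whose posts match abuse categories; the Fisher-z mean of "
    "0.73 says index users and their circles discuss similar drugs."
)
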