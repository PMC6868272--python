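"""Replay the published Maine Coon screening counts.

Reconstructs the 5038 individual records from the printed per-sex score
counts and recomputes prevalence, per-category shares and laterality.
"""

from felhip.datasets import maine_coon_records, maine_coon_score_table
from felhip.demography import laterality_from_marginals, summarize_scores

records = maine_coon_records()
summary = summarize_scores(records)
lat = laterality_from_marginals(maine_coon_score_table())

print(f"cats surveyed:          {summary.n}")
print(f"prevalence:             {summary.prevalence_percent:.1f}%  "
      "(any radiographic sign, maximum score >= 1)")
for k in (1, 2, 3):
    print(f"share with max score {k}: {summary.max_share_percent[k]:.1f}%")
print(f"unilateral among affected: {100 * lat['unilateral_frac']:.1f}%")
print(f"bilateral among affected:  {100 * lat['bilateral_frac']:.1f}%")
# Just over a third of cats show some dysplasia; among them, two thirds
# have both hips involved -- the pattern a shared-liability model predicts.
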