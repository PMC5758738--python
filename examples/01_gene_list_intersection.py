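"""Intersect three disease gene lists to find the shared core.

Builds three synthetic lists (232/143/132 genes, the shape of a typical
three-cancer comparison) that share a planted 17-gene core, then recovers
the core by strict intersection.
"""

from hubpanel.gene_lists import intersect, intersection_report
from hubpanel.synthetic import SyntheticSpec, make_gene_lists

lists, planted_core = make_gene_lists(SyntheticSpec(rng_seed=42))
common = intersect(lists)
report = intersection_report(lists)

print("list sizes:", [len(g) for g in lists])
print("distinct symbols across lists:", len(report))
print("genes in all three lists:", len(common))
print("matches the planted core:", common.members == planted_core.members)
print("first five common genes:", sorted(common.members)[:5])
# The intersection is the candidate biomarker core: genes implicated in all
# three diseases at once. Here it equals the generator's planted truth.
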