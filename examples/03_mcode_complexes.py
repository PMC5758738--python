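"""Detect dense complexes with the MCODE-style algorithm.

Plants three dense modules (16/11/6 nodes at density 0.8) in a sparse
scale-free background, then recovers them as the top-ranked complexes.
"""

from hubpanel.mcode import find_complexes
from hubpanel.synthetic import SyntheticSpec, make_network

spec = SyntheticSpec(rng_seed=1, planted_hub_count=0, component_sizes=())
net, truth = make_network(spec)
complexes = find_complexes(net)

print(f"{len(complexes)} complexes found; top 3:")
print("rank  seed        score  density  size")
for c in complexes[:3]:
    print(f"{c.rank:>4}  {c.seed:<10} {c.score:6.2f}  {c.density:7.2f}  {len(c.members):4}")

for i, planted in enumerate(truth.complex_members, start=1):
    best = max(len(set(planted) & c.members) / len(set(planted) | c.members)
               for c in complexes[:3])
    print(f"planted module {i} (n={len(planted)}): best top-3 Jaccard = {best:.2f}")
# Score = density x size; a Jaccard of 1.0 means a planted module was
# recovered exactly, seed node included.
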