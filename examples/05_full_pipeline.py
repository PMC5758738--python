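"""The whole analysis end to end, from files to reports.

Writes a synthetic input bundle (gene lists, edge list, GMT, universe) to
disk, runs the full pipeline on those files, and prints the summary —
exactly what `hubpanel synth` + `hubpanel run -c config.yaml` do from the
shell.
"""

import json
import tempfile
from pathlib import Path

from hubpanel.pipeline import PipelineConfig, run
from hubpanel.synthetic import SyntheticSpec, make_bundle, write_bundle

with tempfile.TemporaryDirectory() as tmp:
    bundle_dir = Path(tmp) / "bundle"
    write_bundle(make_bundle(SyntheticSpec(rng_seed=42)), bundle_dir)
    summary = run(PipelineConfig(
        gene_lists=[str(bundle_dir / f"{n}.txt")
                    for n in ("colon", "gastric", "esophageal")],
        network=str(bundle_dir / "network.tsv"),
        gmt=str(bundle_dir / "annotations.gmt"),
        universe=str(bundle_dir / "universe.txt"),
        out_dir=str(Path(tmp) / "out"),
        rng_seed=42,
    ))
    keep = ["intersection_size", "n_components", "component_sizes",
            "degree_cutoff", "hub_bottlenecks", "top_complex_sizes",
            "n_significant_terms", "n_term_groups"]
    print(json.dumps({k: summary[k] for k in keep}, indent=1))
    print("\nreport files:", sorted(p.name for p in (Path(tmp) / "out").iterdir()))
# The summary echoes each stage: 17 common genes, a 4-component network,
# the mean+2SD hub calls (all bottlenecks), the three recovered complexes,
# and 18 enriched terms collapsing into 9 kappa groups.
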