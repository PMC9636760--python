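"""Run every stage end-to-end on synthetic data and inspect the manifest.

Equivalent to ``chemotax run-all --outdir chemotax_demo --seed 1 --k 10
--n-clades 2`` from the shell.  The run directory collects the pair table,
SIF/GraphML networks, cluster memberships, the binary matrix, the Newick
tree, clade assignments and a manifest with parameters and row counts.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

from chemotax import RunConfig, SyntheticSpec, run_all

with TemporaryDirectory() as tmp:
    outdir = run_all(
        RunConfig(
            outdir=Path(tmp) / "demo",
            synthetic=SyntheticSpec(seed=1),
            k=10,
            n_clades=2,
        )
    )
    manifest = json.load(open(outdir / "manifest.json"))
    print("artifacts:", ", ".join(manifest["artifacts"]))
    print("\nstage counts:")
    for key, value in sorted(manifest["counts"].items()):
        print(f"  {key}: {value}")
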