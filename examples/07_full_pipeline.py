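"""Run the whole pipeline from one config and inspect the manifest.

Every stage's outputs are digest-recorded; re-running with the same seed
reproduces byte-identical CSVs.
"""

import json
import tempfile
from pathlib import Path

import crocdiag as cd

config = {
    "seed": 7,
    "simulate": {"n_loci": 500, "frac_pa": 0.25, "n_A": 12, "n_B": 12,
                 "n_B_au": 6},
    "filter": {"min_call_rate": 0.8, "depth_tier": 5},
    "panel": {"mode": "fixed_nonfixed"},
    "stats": {"n_permutations": 49},
}

out = Path(tempfile.mkdtemp()) / "run"
manifest = cd.run_pipeline(config, out)
for stage in manifest["stages"]:
    extras = {k: v for k, v in stage.items() if k not in ("stage", "outputs")}
    print(f"{stage['stage']:16s} {len(stage['outputs'])} outputs  {extras}")
print(f"\nmanifest: {out / 'manifest.json'}")
print("Rerunning with the same config and seed reproduces identical digests.")
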