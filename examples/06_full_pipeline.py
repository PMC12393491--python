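"""One-command reproducible pipeline run.

Runs synth -> cluster -> dynamics -> null -> energy -> infer from a
single config and seed, writing plain-text outputs and a manifest whose
digests make the run bit-reproducible.
"""

import json
import tempfile
from pathlib import Path

from capdyn.pipeline import run_pipeline

out_dir = Path(tempfile.mkdtemp(prefix="capdyn_demo_"))
manifest = run_pipeline({
    "seed": 1,
    "out_dir": str(out_dir),
    "synth": {"n_subjects_per_group": 5, "frames_per_subject": 100,
              "n_rois": 40},
    "cluster": {"k_min": 3, "k_max": 5, "n_restarts": 4, "select": True},
    "null": {"enabled": True, "n_surrogates": 5},
})

print(f"run directory: {out_dir}")
for name, digest in sorted(manifest.outputs.items()):
    print(f"  {name:28s} sha256:{digest[:12]}")
print(f"stage seeds: {manifest.stage_seeds}")
null = json.loads((out_dir / "null_comparison.json").read_text())
print(f"\nreal-vs-null silhouette delta: {null['delta_silhouette']:.4f}")
print("re-running with the same config and seed reproduces identical digests.")
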