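"""A small atlas: several anchor positions per class at three noise levels.

Runs the atlas generator on two class-method pairs with two paths each and
prints the manifest summary; the full 17-pair atlas works the same way
(dynamotypes atlas --paths-per-class 5 from the shell).
"""

import tempfile
from pathlib import Path

from dynamotypes import AtlasConfig, generate_atlas

outdir = Path(tempfile.mkdtemp()) / "atlas_demo"
manifest = generate_atlas(
    AtlasConfig(paths_per_class=2, base_seed=0, outdir=outdir),
    classes=[("SN", "SH", "hysteresis"), ("SNIC", "SH", "slow_wave")],
)
print(f"records written: {manifest['n_records']} (gaps: {manifest['n_gaps']})")
print(f"manifest: {manifest['manifest_csv']}")
print(f"checksum: {manifest['checksum']} (bit-reproducible for a fixed base seed)")
print("\neach record is a CSV trace plus a JSON sidecar carrying the class "
      "labels, anchors, noise settings and seed -- enough to regenerate it.")
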