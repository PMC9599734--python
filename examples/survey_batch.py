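"""Survey a batch of structures and compare ligand classes statistically.

Generates a synthetic batch (four ligand classes, noisy coordinates),
scans it into a site-record table exactly as one would scan a directory
of downloaded PDB files, then aggregates the Walker-B–K+1 H-bond lengths
per class and tests the TS-analogue shortening.
"""

import tempfile
from pathlib import Path

from ploopkit import aggregate_by_class, pairwise_comparisons, scan, write_site_records
from ploopkit.io import site_records_frame
from ploopkit.synth import build_batch

with tempfile.TemporaryDirectory() as td:
    out = Path(td) / "batch"
    build_batch(out, n_per_class=15, seed=7)     # 60 PDB files + ground truth
    records, rejects = scan(sorted(out.glob("*.pdb")), compute_sasa=False)
    write_site_records(records, Path(td) / "sites.tsv")
    df = site_records_frame(records)

print(f"{len(records)} accepted sites, {len(rejects)} rejected\n")
summary = aggregate_by_class(df, "wb_k1_distance", resolution_max=2.5, require_qc=True)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\npairwise Mann-Whitney U (BH-adjusted):")
comp = pairwise_comparisons(df, "wb_k1_distance")
print(comp.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# The ts_analog class mean sits below the others and its share of short
# (<2.7 A) H-bonds is the highest -- the batch generator plants exactly the
# class ordering the comparative survey is designed to detect.
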