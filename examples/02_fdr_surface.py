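"""Inspect the 2D local fdr surface over (coverage, VAF).

Builds the surface for a simulated dataset and prints fdr2d at a few
representative statistic pairs.  High-coverage, mid-VAF entries — the
signature of an expressed heterozygous somatic mutation — get small fdr2d;
low-VAF entries (sequencing error) and VAF ~ 1 entries (monoallelic
artifacts, common in single-cell RNA-seq) stay near 1.
"""

import numpy as np

from scsomatic import call_pipeline, evaluate_surface, transform_stats
from scsomatic.simulate import SimulationConfig, simulate_dataset

sim = simulate_dataset(SimulationConfig(seed=42))
result = call_pipeline(sim.cells, sim.bc_sites, sim.germline, seed=7)
surface = result.surface

print(f"grid: {surface.r_grid.shape}, bandwidth = "
      f"({surface.bandwidth[0]:.3f}, {surface.bandwidth[1]:.3f})")
print(f"smoothing points: {surface.n_failure} observed, {surface.n_success} null")
print()
print(" coverage  VAF    fdr2d")
for z1, z2 in [(50, 0.0), (50, 0.02), (50, 0.5), (50, 1.0), (10, 0.5), (200, 0.5)]:
    t1, t2 = transform_stats(z1, z2)
    fdr = evaluate_surface(surface, t1, t2)
    print(f"  {z1:6d}  {z2:4.2f}  {fdr:7.4f}")

# Export for contour plotting
from scsomatic.pipeline import surface_to_frame

df = surface_to_frame(surface)
print(f"\nsurface table: {len(df)} nodes, fdr2d range "
      f"[{df['fdr2d'].min():.4f}, {df['fdr2d'].max():.4f}]")
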