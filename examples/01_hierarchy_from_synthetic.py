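"""Where in the eigenspectrum does each environmental cue live?

Builds a synthetic multi-condition single-cell ensemble with five cues
planted at increasing spectral depths, runs QC -> normalization -> SVD ->
SCALES, and prints each cue's spectral depth and the recovered hierarchy.
A shallower depth means the cue dominates larger-scale transcriptional
variation, i.e. it has higher adaptive priority.
"""

import adaptscales as asc
from adaptscales.synthetic import SyntheticSpec

spec = SyntheticSpec(cells_per_condition=30)  # 48 conditions x 30 cells
counts, truth = asc.simulate_scrna(spec, seed=0)
norm, qc_report = asc.preprocess(counts)
print(f"cells x genes after QC: {norm.n_cells} x {norm.n_genes}")

decomp = asc.decompose(norm, K=30, seed=0)
print(f"top 30 PCs explain {100 * asc.variance_explained(decomp, 30):.1f}% "
      "of transcriptional variance")

result = asc.run_scales(
    decomp, norm.cell_meta, [c.name for c in spec.cues],
    pair_budget=100_000, n_perm=50, seed=1,
)
print("\nspectral depth per cue (window of half-total cumulative MI):")
for cue in spec.cues:
    print(f"  {cue.name:12s} planted at PC {cue.depth:2d} -> "
          f"depth {result.ranking.depths[cue.name]}")
print("\nrecovered hierarchy :", " > ".join(result.ranking.ordering))
print("planted hierarchy   :", " > ".join(truth.planted_ordering))
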