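"""Generate the two-species simulation benchmark and look at its structure.

Creates the matched "mouse"/"human" expression matrices (338 orthologous
genes x 18 hourly time points) with six planted 30-gene classes, then
shows how the leading eigengenes of each species recognize the planted
temporal patterns.
"""

import numpy as np

from svdppcs import decompose, simulate_pair, two_way_polish

mouse, human, truth = simulate_pair(seed=0)
print(f"mouse: {mouse.n_genes} genes x {mouse.n_arrays} arrays")
for cls in ("C1", "C2", "C3", "C4", "C5", "C6"):
    species = sorted(truth.patterns[cls])
    print(f"  {cls}: {len(truth.members(cls))} genes, pattern in {', '.join(species)}")
print(f"  null: {len(truth.members('null'))} genes (noise only)")

for name, mat in (("mouse", mouse), ("human", human)):
    res = decompose(two_way_polish(mat))
    print(f"\n{name} eigengenes (variance fractions):",
          np.round(res.variance_fraction[:4], 3))
    # correlation of each leading eigengene with the planted raw profiles
    for j in range(3):
        v = res.eigengenes[:, j]
        best = max(
            ((cls, sp, abs(np.corrcoef(v, p)[0, 1]))
             for cls in truth.patterns for sp, p in truth.patterns[cls].items() if sp == name),
            key=lambda t: t[2],
        )
        print(f"  eigengene-{j + 1} best matches {best[0]} profile (|r| = {best[2]:.3f})")

print(
    "\nEach species' first three eigengenes recover the three planted pattern "
    "families (sine, gamma density, beta density); the remaining components "
    "are noise."
)
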