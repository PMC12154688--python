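# chromhet

Cell-to-cell **conformational heterogeneity** of 3D genome organization, for
ensembles of single-cell chromatin conformations.

Modern chromatin models — polymer simulations fitted to bulk Hi-C, structure
populations selected against contact maps, models built from single-cell
Hi-C — all produce *ensembles* of 3D conformations, one per model nucleus.
Comparing such ensembles is hard: their length units differ, their bead
resolutions differ, and a single Hi-C-style summary hides how much structure
varies from cell to cell.  `chromhet` quantifies that variability with one
number per genomic scale and provides the machinery needed to compare models
fairly across resolutions.

## The metric

For one cell *k*, let ⟨Rs⁽ᵏ⁾(s)⟩ be the Euclidean distance between chromatin
loci separated by genomic distance *s*, averaged over all locus pairs at that
separation within the cell.  Across an ensemble of *n* cells:

- **C.H.(s)** = √( (1/n) Σₖ ( ⟨Rs⁽ᵏ⁾(s)⟩ − R̄s(s) )² ) — the population
  standard deviation of the per-cell curves (units of the model);
- **Relative C.H.(s)** — the same standard deviation after dividing each
  cell's curve by the ensemble mean R̄s(s): dimensionless, scale invariant,
  comparable across models.

An ensemble of identical nuclei scores exactly zero, however convoluted each
conformation is: the metric isolates *between-cell* variability.

Supporting components:

- **Lattice-path model of intra-TAD folding** (`chromhet.mctad`): a TAD is an
  N×N×N cube of bins; chromatin conformations are axis-aligned unit-segment
  paths threading the cube and its neighbour.  The spread σ of subchain
  end-to-end distances at one-TAD contour length calibrates how much
  heterogeneity a finer-resolution model would show.
- **Resolution up-conversion** (`chromhet.upconvert`): shifts each cell's Rs
  curve by one Normal(0, Σ) offset, Σ = C_conv·σ, to emulate the spread of a
  higher-resolution model without re-simulating it.
- **Reference ensembles** (`chromhet.reference`): orientation-random
  approximate 3D Hilbert curves (compact, space-filling packing), freely
  jointed chains (ideal polymer; Relative C.H. → 1/√3 ≈ 0.58 for long
  chains), and sphere-confined random walks.
- **I/O and workflows** (`chromhet.ensemble`, `chromhet.workflow`,
  `chromhet` CLI): a documented TSV/XYZ schema for bead chains, homolog-chain
  merging, trajectory-snapshot resampling with error bars, and a two-ensemble
  comparison (e.g. wild type vs lamins-depleted nuclei).

## Worked example

```python
import numpy as np
from chromhet import (ReferenceEnsembleSpec, generate_reference_ensemble,
                      compute_rs_profiles, compute_relative_ch,
                      fit_scaling_exponent, enumerate_paths_exhaustive,
                      compute_sigma)

# 18 freely jointed chains of 2047 unit segments, 10 kb per segment
ens = generate_reference_ensemble(
    ReferenceEnsembleSpec(kind="fjc", n_replicas=18, n_segments=2047, seed=1))
profiles = compute_rs_profiles(ens)
het = compute_relative_ch(profiles)
for s in (1, 10, 100, 1000):
    i = int(np.searchsorted(het.grid.separations_beads, s))
    print(f"s = {s*10:>5d} kb: relative C.H. = {het.relative_ch[i]:.3f}")
alpha, sd = fit_scaling_exponent(profiles, fit_range=(2, 400))
print(f"scaling exponent alpha = {alpha:.3f} +/- {sd:.3f}")

paths = enumerate_paths_exhaustive(2, "two_cubes")
print(f"two-cube path census (N=2): {paths.n_paths}")
print(f"sigma(2x2x2) = {compute_sigma(paths).sigma_au:.2f} a.u.")
```

prints

```
s =    10 kb: relative C.H. = 0.000
s =   100 kb: relative C.H. = 0.028
s =  1000 kb: relative C.H. = 0.076
s = 10000 kb: relative C.H. = 0.293
scaling exponent alpha = 0.498 +/- 0.052
two-cube path census (N=2): 36864
sigma(2x2x2) = 0.31 a.u.
```

Reading it: at the 10-kb resolution limit every chain segment has the same
length, so the cells are indistinguishable and the heterogeneity is zero; it
grows with genomic separation and rises sharply near the chain ends, where
only a few locus pairs average out the noise.  The fitted Rs ∝ s^α exponent
recovers the ideal-chain value α ≈ 0.5.  The lattice-path census and σ are
the inputs for up-converting a TAD-resolution model (118-kb beads) to ~14-kb
resolution.

The same pipeline runs from the shell:

```bash
chromhet generate --kind fjc --replicas 18 --segments 2047 --seed 1 --out fjc.tsv
chromhet heterogeneity --input fjc.tsv --label fjc --resamples 10 --seed 1 --outdir out/
chromhet mctad --n-side 2 --scope two_cubes --exhaustive --out mctad.tsv
chromhet compare --input-a wild_type.tsv --input-b depleted.tsv --out cmp.tsv
```

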