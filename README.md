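# morphuniq

Landmark-based geometric morphometrics for testing which biological factor
best partitions a morphospace. The package was built around a question from
insect evolutionary ecology: in the walking-stick insect *Timema cristinae*,
whose host-plant ecotypes are partway through ecological speciation, is
mandible (trophic) shape divided by host plant, by population, by rearing
environment — or by sex? It implements the full analysis chain needed to
answer that question on 2-D landmark data, together with a synthetic
landmark generator that emulates the study design (189 lingual-view
specimens across six populations × sex × field/lab rearing), so every method
can be exercised and validated end to end without the original micrographs.

## Methods implemented

- **Generalized Procrustes superimposition (GPA)** — full-Procrustes
  convention (centring, unit centroid size `CS = √Σᵢ‖xᵢ − x̄‖²`, orthogonal
  rotation with reflections excluded), iterated to a consensus; deterministic
  principal-axis orientation.
- **Thin-plate-spline shape variables** — bending-energy matrix from
  U(r) = r² log r² on the consensus; its k − 3 principal warps plus a
  2-D uniform (affine) basis give 2k − 4 shape variables per specimen
  (16 partial-warp scores + 2 uniform components for k = 11), with
  deformation-grid visualisation data.
- **Relative warps** — unweighted PCA (α = 0) of the shape variables.
- **Allometric size correction** — Shapiro–Wilk-guided log transform of
  centroid size, Welch t for group size contrasts, and MANCOVA residuals
  with a Wilks pre-test of the sex × size interaction.
- **Morphological Uniqueness (MU)** — per relative warp, one minus the
  integral of the pointwise minimum of the two groups' Gaussian kernel
  densities on a common grid; weighted by eigenvalue proportions and summed:
  `MU = Σᵢ wᵢ (1 − overlapᵢ)` ∈ [0, 1]. Significance by re-assigning
  specimens to groups of the original sizes (with replacement, 1000×);
  pairwise matrices and per-RW dominance tables for multi-level factors.
- **Model-based clustering** — diagonal Gaussian mixtures fitted by
  restarted EM with per-variable variance floors, scored by a
  Cheeseman–Stutz approximation to the marginal likelihood for selecting
  the number of shape clusters.
- **Type-III Wilks MANOVA** — effect-coded SSCP model comparison
  (Λ = |E|/|E+H|, Rao's F), partial η² = 1 − Λ^(1/s), observed power from
  the noncentral F; nested designs (population within host); bootstrap
  trajectory-angle comparison of group principal axes.
- **Gene-flow influence regression** — influence index
  (prop_focal + prop_adjacent)/distance and the regression of per-population
  shape dispersion (SEM of RW1–RW3) on it.

## Worked example

The numbered drivers under `analysis/` run the whole chain on the emulated
study and write tables under `results/`:

```sh
python analysis/01_simulate_study.py 1   # 189 specimens, TPS + factor CSV
python analysis/02_superimpose.py        # GPA + centroid-size sex contrast
python analysis/03_shape_variables.py    # 18 shape variables, size correction, RWs
python analysis/04_uniqueness.py 1       # MU dominance + resampling tests
python analysis/05_clustering.py 1       # mixture selection + assignments
python analysis/06_manova.py 1           # transplant MANOVA, trajectories, nested
python analysis/07_geneflow.py           # dispersion vs influence
```

Selected output (seed 1):

```
centroid size: females 990.9 um, males 874.8 um, Welch t(69.9) = 11.96, p = 1.4e-18
18 shape variables per specimen (16 partial-warp scores + 2 uniform)
size transform: log; sex x size interaction p = 0.402 -> single common slope
overall MU by factor: sex=0.468, host=0.195, population=0.308, rearing=0.188
factor ranking: sex > population > host > rearing
selected K = 2; best classification 6071186736331959.00x more probable than the runner-up
  cluster 1: n = 48, sexes {'F': 48}, 100% assigned with posterior > 0.95
  cluster 2: n = 141, sexes {'M': 141}, 100% assigned with posterior > 0.95
sex                    0.049  61.533  18.0  57.0  0.000   95.106   1.000
slope = -4.36e-06, r2 = 0.382, p = 0.267
```

Reading it: females carry significantly larger mandibles; after allometric
correction sex still partitions the morphospace best (MU 0.468 vs ≤ 0.31 for
every other factor), the unsupervised mixture recovers exactly two shape
clusters that are the two sexes, the transplant MANOVA attributes most
residual shape variance to sex (η² ≈ 95%), and shape dispersion shows no
relationship with the gene-flow proxy — the generator injects none.

The same chain is available as a CLI (`morphuniq simulate`, `morphuniq all
landmarks.tps --factors factors.csv --seed 1 …`) for use on real TPS/CSV
landmark files.

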