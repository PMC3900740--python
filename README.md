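# xtal2d

Projection difference-map titration analysis for electron crystallography of
2D membrane-protein crystals.

## The problem

Two-dimensional crystals of the archaeal Na⁺/H⁺ antiporter MjNhaP1 change
conformation when sodium binds: a pair of half-helices (5c/12e) shifts
laterally by ~2 Å, TMH 6 straightens, TMH 13 tilts, and half-helix 5e gains
order.  On the crystal lattice every molecule is either in the apo
(proton-bound) or the Na⁺-bound state, so a projection map at a given Na⁺
concentration is a population average, and the strength of the
positive/negative peak pairs in a difference map against the sodium-free
reference is a direct readout of bound-state occupancy.  Titrating Na⁺ and
counting difference-peak contour levels therefore yields apparent
dissociation constants — crystallographic binding measurements.  Because Na⁺
and H⁺ compete for a common site, the apparent constant is pH dependent
(~30 mM at pH 8, ~280 mM at pH 4, a ~10-fold shift).

`xtal2d` implements that entire analysis as a reusable, tested pipeline, plus
a synthetic-crystal generator that emulates the experiment end to end, so
every stage is verifiable without raw image data:

1. **synthetic crystals** — a Gaussian-rod model of the 13-TMH protomer
   (p2 dimer, 81.2 × 104.2 Å cell drifting to 80.6 × 107.9 Å at full
   occupancy), two conformational states mixed by the competition isotherm
   θ = c / (c + K_app), K_app = K_Na · (1 + 10^(pK − pH)); per-lattice
   reflection noise, random phase origins and scales;
2. **merging** — exhaustive-search phase-origin alignment, least-squares
   amplitude scaling, vector averaging of ≥6 lattices with phase-residual
   reporting;
3. **difference maps** — resampling to a common cell, subtraction, random
   half-split controls that fix an absolute contour step of 1.5σ(control)
   (background ±2 levels ≈ 3σ), peak-to-trough contour counting in declared
   helix regions, control-background zeroing, and centroid-based helix
   displacement estimation;
4. **affinity fitting** — a statsmodels-style `TitrationModel` whose `fit()`
   returns a `FitResult` with the apparent K_D, h_max, bootstrap 68%
   interval and a `summary()` table; plus fold-ratio and across-region
   consistency reports.

## Worked example

```bash
xtal2d reproduce --seed 17 --out-dir out/
```

simulates both titrations (six lattices per condition), writes maps (CCP4),
counts (CSV), fits and figures, and prints:

```json
{
  "kd_app_mM": {
    "8": {"set1_5c12e": 33.97, "set2_TMH6": 28.36, "set3_13_5e": 33.77},
    "4": {"set1_5c12e": 340.50, "set2_TMH6": 321.55, "set3_13_5e": 300.90}
  },
  "kd_ratio": 9.52,
  "displacement_A": 1.97
}
```

Reading this: the three difference-peak sets at pH 8 give nearly identical
apparent constants around the 30 mM ground truth; at pH 4 the same regions
give ~300–340 mM against the 280 mM ground truth (acid conditions saturate
less of the ladder, so estimates scatter more); the acid/base ratio ≈ 9.5
recovers the ~10-fold competition effect; and the centroid estimator reads
the 2 Å 5c/12e shift off the noiseless state maps to 1.97 Å.

The same stages are scriptable from Python:

```python
from xtal2d.pipeline import run_titration_replicate
rep = run_titration_replicate(ph=8.0, ladder=(0, 20, 50, 100, 250, 500), seed=1)
print(rep.fits["set1_5c12e"].summary())
```

Individual CLI stages: `xtal2d simulate`, `merge`, `map`, `diffmap`,
`titrate` (see `--help` for each).

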