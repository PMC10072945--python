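# retmosaic

Agent-based simulation of retinal mosaic formation.

Most retinal cell types arrange their somata in semi-regular planar patterns
("retinal mosaics"). `retmosaic` models how such mosaics can self-organize
during development from purely local, homotypic chemical interactions. Cells
are spherical agents in a thin slab; every cell type secretes its own
diffusible substance (explicit finite-difference diffusion on a 3D voxel
lattice), and three mechanisms act on the resulting concentration fields:

* **CF — cell fate determination**: the substance of an already
  differentiated cell inhibits nearby undifferentiated cells from adopting
  the same type (lateral inhibition);
* **CD — programmed cell death**: a cell removes itself when its own-type
  concentration exceeds a threshold, thinning homotypic clusters (retinal
  ganglion cells lose ~60–65% of their initial population this way);
* **CM — tangential migration**: above a lower threshold, a cell moves step
  by step against the in-plane gradient of its own substance, drifting away
  from homotypic neighbours.

The package bundles the 43-type retinal ganglion cell (RGC) catalogue
(per-type start/adult densities and per-condition thresholds), threshold
calibration to the observed death rates, the two-layer starburst amacrine
cell (SAC) experiments (one shared vs two independent guidance cues), and
the spatial statistics used to score mosaics.

**Who it is for**: computational neuroscientists and developmental biologists
who want to test mechanistic hypotheses about mosaic formation, and anyone
needing the nearest-neighbour mosaic statistics on their own cell-position
tables.

## The statistics

For a planar point pattern, with `d_i` the distance from cell *i* to its
nearest neighbour:

* **Regularity Index**: `RI = mean(d) / sd(d)` (sample s.d.). Uniform-random
  patterns score 1.8–2; regular mosaics score higher; a perfect lattice is
  reported as infinite regularity.
* **Exclusion factor** between two populations A and B: the fraction of A
  cells whose nearest B cell lies beyond a fixed exclusion diameter (32 µm
  here, ≈3 SAC soma diameters), symmetrized over both directions. 1 = perfect
  exclusion, 0 = coincident populations.

## Worked example

Run the death-only condition of the RGC model at desk scale and score it:

```python
import dataclasses
import retmosaic as rm
from retmosaic import experiments as xp
from retmosaic.rgc import calibrate_thresholds, load_catalogue, make_condition

catalogue = load_catalogue()            # the 43 RGC types
scale = dict(core=400, margin=100, voxel_size=4.0)

# calibrate per-type death thresholds to the observed ~65% developmental loss
params, table = calibrate_thresholds("D", catalogue, target_death_rate=0.65,
                                     iterations=6, seeds=(1,), **scale)

# run three replicate simulations to death steady state
config, types, _ = make_condition("D", catalogue, **scale)
results = [rm.run(dataclasses.replace(config, seed=s), types, params)
           for s in (1, 2, 3)]

per_type = xp.pooled_type_ri(results)   # NN distances pooled across seeds
print(f"death rate {100 * sum(r.death_rate for r in results) / 3:.1f}%")
print(f"across-type average RI {per_type['ri'].mean():.2f}")
print(per_type[per_type.density_mm2 > 100][["name", "density_mm2", "ri"]])
```

prints (seeds 1–3):

```
death rate 62.1%
across-type average RI 3.81
            name  density_mm2        ri
2   on-off_dsgcc   108.333333  3.959774
5     on-off_led   197.916667  4.055868
19          on_o   114.583333  3.573546
34         off_j   183.333333  4.436222
35    off_mini_j   360.416667  4.907825
```

About 62% of the initial 8600 cells/mm² have removed themselves by steady
state (the observed developmental loss is 60–65%), and the surviving mosaics
are clearly more regular than random (RI ≈ 3.8 across types vs 1.8–2.0 for
uniform-random patterns). With migration enabled (condition `"FDM"`) denser
types become far more regular than sparse ones and the density–regularity
relation turns into a strong linear correlation (Pearson r ≈ 0.86 across
the 43 types in the full replication run).

The same machinery is available from the shell:

```bash
retmosaic rgc --condition FDM --seeds "1 2 3"   # runs + CSV/JSON artifacts
retmosaic metrics positions.csv                 # score any position table
retmosaic sac --cue-mode both                   # paired SAC experiments
```

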