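# bprw — bimodal persistent-random-walk analysis of larval crawling

`bprw` quantifies the crawling behaviour of *Drosophila* larvae (or any
2-D crawler with a stop-and-turn gait) from centroid trajectories, for
researchers phenotyping movement in disease-model and mutant screens.
Larvae crawl in two modes: an **active crawling** phase that is a
persistent random walk — Weibull step lengths ℓ ~ Weib(k, λ), Gaussian
turning angles θ ~ N(0, σ_c) — and a still-standing **reorientation**
phase with broad exit turns θ ~ N(0, σ_r).  The package extracts this
phenotype from raw tracks, simulates matched trajectories from it, and
compares strains.

The pipeline:

1. **Smooth** each track at the imaging resolution limit r: runs of
   consecutive samples within a·r of the run's first member (a rising
   0.1 → 1.0, then iterated at r to a fixed point) collapse to their
   weighted centroid; each smoothed point keeps m, the number of raw
   samples it absorbed, so m·dt is dwell time.
2. **Detect reorientations** as the high-side outliers of each track's m
   values (iterative modified Thompson tau, α = 0.05), after excluding
   pathological rests (dwell > 14 s by default).
3. **Fit the phenotype**: reorientation frequency; Gamma dwell models per
   phase; Weibull steps and zero-mean Gaussian turning angles for the
   crawl phase; Grubbs-cleaned Gaussian σ for the turn across
   reorientation events; phase agilities (inverse mean dwell) per track,
   reported mean ± SEM.
4. **Simulate** trajectories from any phenotype (event-level bimodal PRW,
   rendered to camera frames with head-sweep centroid jitter), estimate
   the crawl-phase **persistence length** from the worm-like-chain
   end-to-end relation ⟨R²⟩(L) = 2l_pL − 2l_p²(1 − e^(−L/l_p)), and
   compute population **MSD** curves with 1σ bands from repeated matched
   simulations.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Simulate a wild-type-like strain, re-analyse the rendered tracks, and
estimate its persistence length:

```python
from bprw import CrawlParameters, write_parameters
write_parameters(
    CrawlParameters(
        reorientation_frequency=0.10,
        crawl_time_gamma=(16, 0.25),    # dwell mean 4 s per crawl point
        reorient_time_gamma=(4, 5.0),   # dwell mean 20 s per reorientation
        step_weibull=(1.5, 0.5),        # mm
        crawl_angle_sigma=0.3,          # rad
        reorient_angle_sigma=1.2,       # rad
    ),
    "wildtype.json",
)
```

```sh
$ cat config.json
{"n_tracks": 25, "duration": 1800.0, "dt": 2.0, "r": 0.015, "seed": 1,
 "resolution_limit_r": 0.015, "rest_threshold": "inf"}

$ bprw simulate wildtype.json --config config.json --out-dir sim
wrote sim/tracks.csv (25 tracks)

$ bprw analyze sim/tracks.csv --config config.json --out-dir analysis
wrote analysis/parameters.json

$ bprw persistence analysis/parameters.json --seed 1 --n-tracks 200 --n-steps 500
persistence length: 10.530 mm
```

`analysis/parameters.json` then contains the recovered phenotype
(compare with the inputs above):

```json
{
  "reorientation_frequency": 0.1035728105041485,
  "crawl_time_gamma":    [9.066028451811144, 0.4374942745791281],
  "reorient_time_gamma": [4.334866233371005, 4.50659797710148],
  "step_weibull":        [1.553780990081556, 0.5169530254909536],
  "crawl_angle_sigma":   0.31479838170421887,
  "reorient_angle_sigma": 1.1479614591217735
}
```

Reading the numbers: 10.4% of smoothed points are reorientations (truth
10%); the crawl dwell Gamma has mean 9.066 × 0.437 ≈ 3.97 s (truth 4 s —
the Gamma *shape* is not individually recoverable after 2 s frame
quantisation, the mean is) and the reorientation dwell mean is 19.5 s
(truth 20 s); steps and both angle widths come back within a few
percent.  The persistence length 10.5 mm sits in the 8–11 mm range
characteristic of larval crawling and exceeds the ~4.5 mm the simulated
larva travels between reorientations (0.1 frequency × 0.45 mm mean
step), which is why reorientation statistics, not persistence, dominate
strain differences.  `analysis/per_track.csv` carries per-animal
frequencies and agilities (e.g. crawl agility ≈ 0.26 s⁻¹ = 1/3.9 s);
`bprw compare strainA.json strainB.json` tabulates strains side by side,
and `bprw msd tracks.csv --params wildtype.json` adds a simulated 1σ
band to the measured MSD.

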