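# smfret

Single-molecule FRET trace analysis for conformational-state studies, built
around the experiment that motivated it: resolving the conformational
states of individual actin molecules (monomeric G-actin and protomers
within F-actin filaments) by intramolecular Förster resonance energy
transfer under TIRF microscopy.

A donor and an acceptor dye on one protein report their separation through
the FRET efficiency

```
E = I_a / (I_a + γ · I_d)          r = R0 · (1/E − 1)^(1/6)
```

where `I_a`, `I_d` are the background-subtracted acceptor and donor
intensities, γ is the detection-correction factor measured per condition as
the median of |ΔI_a/ΔI_d| across the acceptor photobleach step, and `R0` is
the Förster radius of the dye pair (default 5.1 nm). Pooled per-frame
efficiencies from hundreds of molecules form a multi-modal distribution;
fitting a sum of 2–3 Gaussians by maximum likelihood decomposes it into
conformational states (labelled, from high to low efficiency, `g`, `fg`,
`f`). Because photobleaching ends each record after a few seconds while the
states persist for minutes, state lifetimes are estimated from censoring
arithmetic: the fraction of records that catch at least one transition
approximates `T_obs / τ`.

The package covers the full chain:

| module | role |
| --- | --- |
| `smfret.simulate` | generative model: hidden-state traces, bleaching, camera noise, dual-view movies, condition presets with ground truth |
| `smfret.imaging` | spot detection, donor→acceptor view registration, aperture-photometry trace extraction from TIFF stacks |
| `smfret.processing` | moving-average smoothing, photobleach change-point detection, FRET-pair selection, γ estimation, efficiency computation |
| `smfret.mixture` | Gaussian-mixture EM on pooled efficiencies, BIC model-order selection, per-frame state assignment |
| `smfret.kinetics` | flicker-suppressed transition counting, censored-fraction lifetime, Förster distance conversion |
| `smfret.pipeline` / `smfret.cli` | one-config orchestration with manifest + checksums; `smfret` console command |

## Worked example

```python
from smfret.pipeline import validate_config, run_pipeline

config = validate_config({"mode": "simulate", "preset": "factin", "seed": 3})
manifest = run_pipeline(config, "runs/factin")
```

`runs/factin/report.json` then contains (values printed by the run above):

```
"K": 3,
"means":   [0.369645, 0.540529, 0.747221],
"state_labels": ["f", "fg", "g"],
"gamma": 0.998941,
"distances_nm": {
  "per_state": {"f": 5.5745, "fg": 4.9638, "g": 4.2571},
  "mean_frame_weighted": 5.1366, ...
}
```

Three conformational states were resolved from the pooled efficiency
histogram of a 374-molecule synthetic F-actin ensemble; the fitted peak
positions sit at the generating values (0.37/0.54/0.75), γ recovers the
simulated detection balance of 1.0, and the frame-weighted mean efficiency
converts to a ~5.1 nm mean inter-dye distance. The same run reports the
censored-fraction kinetics (`kinetics.lifetime_s`, with its binomial 95%
interval) and writes every intermediate artifact (traces, per-molecule
selection outcomes, pooled histogram, state assignments) next to the
report, plus a manifest with SHA-256 checksums — rerunning with the same
config and seed reproduces every artifact byte for byte.

The same stages are available from the shell:

```
smfret simulate --preset factin --seed 1 --out sim/
smfret process  --traces sim/traces.csv --out proc/
smfret states   --processed proc/ --k 2,3 --seed 7 --out states/
smfret report   --states states/ --processed proc/ --r0 5.1 --out report.json
smfret extract  --movie movie.tif --psf-sigma 1.2 --threshold-sd 5 --out traces.csv
smfret run      --config run.json
```

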