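# besselflow

A virtual image-encoded flow cytometer built around a scanning
Bessel–Gaussian beam.

Real instruments of this kind image cells in flow without labels: an
acousto-optic deflector sweeps a Bessel–Gaussian focus across a microfluidic
channel once every few microseconds, a slit selects a thin section of the
flow axis, and a single photomultiplier records the transmitted light. Each
scan yields one line of a 2D transmission image encoded in time; the long
depth of focus of the Bessel beam keeps cells sharp throughout the channel,
at the cost of concentric sidelobes that mix neighbouring positions into
every sample. `besselflow` simulates that whole signal chain on synthetic
phantoms and undoes the sidelobe mixing by linear inversion, so the imaging
model, the waveform features used for sorting, and the sort metrics can be
studied quantitatively with known ground truth.

## What the package does

1. **Beam model** (`besselflow.beam`) — approximates the Bessel–Gaussian
   intensity profile by a weighted comb of delta functions at the extrema of
   J0. The weight of the sidelobe at radial position `u_l / k_r` is
   `J0(u_l)^2 · exp(−2 u_l^2 / (k_r w0)^2)`, normalized so the main lobe has
   weight 1. The default radial wavenumber is chosen so the main-lobe
   intensity FWHM is 1.2 µm.
2. **Phantoms** (`besselflow.phantom`) — 2D transmission maps for polystyrene
   beads (dark rim, bright centre), granular cells, and elongated algal
   colonies, plus seeded scene generation for timed mixtures. Transmission
   levels can be set directly or derived from an index contrast via the
   Fresnel two-interface formula `f = 4 n0 (n0+Δn) / (2 n0 + Δn)^2`.
3. **Forward model** (`besselflow.forward`) — maps each sample time to a
   (scan position, flow position) pair, integrates the phantom over the slit
   height, applies the sidelobe comb, and adds a fixed per-scan background
   ripple and white noise. A second channel emulates a two-slit transit-time
   velocimeter. Defaults: 5 µs scan period over a 40 µm field of view
   (scan speed 8 m/s), 25 MS/s sampling (125 samples per scan, 0.32 µm
   pitch), 1.5 µm slit, flow speeds 10–25 cm/s.
4. **Reconstruction** (`besselflow.reconstruct`) — the per-scan signal is a
   Toeplitz mixture of the transmission line with the comb; on the extended
   grid (125 in-field samples plus 63 padding samples per side → 251×251
   matrix) the operator is symmetric, unit-diagonal and diagonally dominant
   (condition number ≈ 2.31). With the out-of-field transmission constrained
   to background the in-field block solves exactly: the forward→inverse
   round trip is accurate to ~1e−15.
5. **Features and sorting** (`besselflow.features`) — per event:
   `T1` (envelope duration; `T1·v` = object length), per-scan widths `T2`
   (`max T2 · v_scan` = object width), positive-peak count `N` (granularity
   proxy), and the flow speed `v` from the velocimeter channel. Speed
   multiplication removes the 2.5× spread that the flow-speed range would
   otherwise smear into every temporal feature. Gates are axis-aligned
   bounds or a KDE histogram-valley threshold; sort quality is reported as
   purity, yield, and enrichment (odds ratio) against ground truth.
6. **Config + CLI** (`besselflow.config`, `besselflow.cli`) — YAML-configured
   runs, full provenance (`run_log.json` with a config hash and seed), and
   subcommands `simulate | reconstruct | features | sort | run`.

## Worked example

A single 10 µm bead crossing at 20 cm/s (known ground truth), synthesized,
background-subtracted, and summarized:

```python
from besselflow import (AcquisitionParams, BeamParameters, ObjectSpec,
                        ScenePlan, comb_weights, detect_events,
                        extract_features, subtract_background,
                        synthesize_waveform)

beam = BeamParameters()            # main-lobe FWHM 1.2 um
comb = comb_weights(beam)
acq = AcquisitionParams()          # 5 us scans, 125 samples each, 1% noise
obj = ObjectSpec(kind="bead", diameter=10.0, speed=20.0,
                 arrival_time=600.0, bright_spot=True)
rec = synthesize_waveform(ScenePlan(objects=[obj], seed=0), comb, acq, seed=0)
clean = subtract_background(rec)
table = extract_features(clean, detect_events(clean))
print(table[["T1_us", "T2_max_us", "speed_cm_s", "L_um", "W_um"]].round(3))
```

prints (exactly reproducible at this seed):

```
   T1_us  T2_max_us  speed_cm_s    L_um    W_um
0  60.336      1.265      20.192  12.183  10.119
```

The estimated speed is within 1% of the true 20 cm/s; the recovered width
`W = T2_max · v_scan` is 10.12 µm for the 10 µm bead; the recovered length
`L = T1 · v` is 12.18 µm — the 10 µm object broadened by the 1.5 µm slit,
within one scan of travel (1 µm) of the expected 11.5 µm.

Scaling up to a sorting experiment — a 1:1 mixture of 200 beads of 7 µm and
200 of 10 µm (size CV 3%, speeds uniform in 10–25 cm/s, 1% noise), gated on
the size product `(T1·v)·(T2·v_scan)` at the histogram valley:

```python
from besselflow import bead_mixture_config, run_pipeline
report = run_pipeline(bead_mixture_config(7.0, 10.0, n_each=200, seed=1)).report
print(report.to_dict())
```

sorts all 200 large beads with 0 contaminants at this seed: purity 100.0%,
yield 100.0%. The same pipeline covers a 7 vs 15 µm mixture and a 1:50
spike of granular 13 µm cells into smooth 9 µm cells
(`leukemia_config()`), gated jointly on length `T1·v` and granularity
`N·v`.

As a purity arithmetic reference: sorting 128 events of which 124 are true
targets gives a purity of 100·124/128 = 96.9% ≈ 97%; sorting 253 with 248
targets gives 98.0%.

### Command line

```sh
besselflow run --config examples/beads.yaml --seed 1 --out scratch/run1
# or stage by stage
besselflow simulate --config cfg.yaml --out out/
besselflow features --config cfg.yaml --waveform out/waveform.h5 --out out/
besselflow sort     --config cfg.yaml --waveform out/waveform.h5 --out out/
besselflow reconstruct --config cfg.yaml --waveform out/waveform.h5 --out out/
```

`reconstruct` writes one 32-bit float TIFF (plus PNG preview and JSON
sidecar) per detected event; `sort` writes `decisions.csv` and
`sort_report.json`.

## Documentation

See `docs/methods.md` for the full model description, parameter table,
numerical choices, and limitations.
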