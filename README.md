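# ardecon

Restore single-particle cryo-EM density maps that suffer anisotropic
resolution from preferred particle orientation. The pipeline builds an
optical transfer function (OTF) from the directional Fourier shell
correlation (dFSC) of two half-maps and deconvolves the full map with an
entropy-regularized iterative solver, partially recovering information in
under-sampled Fourier regions (e.g. a missing cone).

A synthetic-data module generates phantoms degraded by controllable
Fourier-coverage loss, so every stage is testable without external datasets.

## Layout

| module                | purpose                                                        |
|-----------------------|----------------------------------------------------------------|
| `ardecon.volume`      | cubic volumes, MRC2014 I/O, DC-centered FFT, masks, filters    |
| `ardecon.dfsc`        | conical-shell directional FSC, rendered dFSC volume, resolution |
| `ardecon.otf`         | Gaussian transfer construction and OTF assembly                |
| `ardecon.decon`       | entropy-regularized deconvolution, full pipeline, grid search  |
| `ardecon.synthetic`   | phantoms, orientation tables, missing-cone degradation         |
| `ardecon.cli`         | `ardecon` command-line interface                               |

## Command line

Full pipeline (two half maps + full map in, deconvolved map out):

```sh
ardecon run --half1 H1.mrc --half2 H2.mrc --map FULL.mrc \
    [--mask M.mrc] [--ndirs 500] [--apex 40] [--threshold 0.143] \
    [--smoothing 0.5] [--nonlinearity 1e4] -o OUT.mrc
```

This writes `OUT.mrc` plus the dFSC volume, the OTF, per-direction FSC
curves (CSV) and a JSON parameter/resolution log next to it.

Other subcommands:

```sh
ardecon simulate --shape 64 --cone 30 --noise 0.1 --seed 0 -o DIR/
ardecon dfsc  --half1 H1.mrc --half2 H2.mrc -o DFSC.mrc
ardecon otf   --half1 H1.mrc --half2 H2.mrc -o OTF.mrc
ardecon tune  --half1 H1.mrc --half2 H2.mrc --map FULL.mrc \
              --reference REF.mrc -o SCORES.csv
ardecon mask  --map FULL.mrc --threshold 0.02 -o MASK.mrc
ardecon reference --map DECON.mrc --resolution 6 -o REF.mrc
```

`simulate` produces a phantom, Fourier-coverage weights with an empty
double cone, two independently noised half maps, the full map and a
tilt-filtered orientation table (STAR text). `tune` screens the
smoothing/nonlinearity grid against a reference map and reports the best
pair. `reference` lowpass-filters and normalizes a deconvolved map for use
as an external refinement reference.

## Notes

- All Fourier-domain volumes are DC-centered; voxel `(N//2, N//2, N//2)`
  is the zero-frequency component.
- Pipeline defaults: 500 Fibonacci
  directions, 40° cone apex, FSC threshold 0.143, smoothing 0.5,
  nonlinearity 1e4, 20-voxel mask edge, 6 Å reference lowpass.
- The solver is deterministic (fixed initialization, no randomness); its
  objective trace is non-increasing by construction.
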