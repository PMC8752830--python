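# viscofit

Viscoelastic parameterization of quasi-static AFM spherical-indentation
force curves.

`viscofit` fits generalized Maxwell (stiffness-side) and generalized
Kelvin–Voigt (compliance-side) spring/dashpot models to force curves
through the Lee–Radok hereditary (convolution) integral, selects the
number of viscoelastic terms, and converts fitted models into
multi-timescale storage-modulus / loss-modulus / loss-angle spectra with
Student-t confidence bands. A built-in simulator generates synthetic
constant-velocity indentation curves (50 kHz sampling, optional Gaussian
force noise) so every stage is testable without instrument data.

## Highlights

- **Two fitting strategies** over the same normalized SSE cost:
  - *iterative term introduction* — grow the model one arm at a time,
    warm-starting from the previous optimum and randomizing only the new
    arm's parameters inside decade-spaced timescale windows;
  - *open search* — all parameters fitted simultaneously from random
    starts.
  Both use seeded multistart bounded trust-region least squares in
  log10-parameter space; every fit is a pure function of
  (curve, config, seed).
- **Exact elastic limit**: the hereditary convolution is discretized by
  integrating the time derivative onto the analytic kernel, so a zero-arm
  model reproduces the closed-form Hertz force to machine precision and
  each exponential arm costs O(n) via a recursive filter.
- **Term-count selection** on log-spaced residuals with extra weight on
  the final decade (long-timescale improvements are the selection signal).
- **Harmonics**: spectra on the experiment-implied band
  (1/duration … sampling rate), frequency-domain averaging across curves,
  95% Student-t bands (mean-CI or observation style).
- **Hertz baseline**: closed-form pseudo-elastic Young's modulus fits,
  1.5·IQR box statistics, Welch's t-test.

## CLI

```sh
# simulate 5 synthetic curves from a random 3-arm ground truth
viscofit simulate --arms 3 --n 5 --seed 7 --out curves/

# fit them (iterative ladder up to 3 terms, 50 restarts per stage)
viscofit fit --input curves/curve_0000.csv --input curves/curve_0001.csv \
    --method iterative --max-terms 3 --attempts 50 --seed 1 --out fits/

# aggregate fitted models into a spectrum with 95% bands
viscofit harmonics --fits fits/curve_0000.fit.json \
    --fits fits/curve_0001.fit.json --duration 0.1 --out spectrum.csv

# pseudo-elastic Hertz statistics
viscofit hertz --input curves/curve_0000.csv --out hertz.json

# desk-scale iterative-vs-open benchmark
viscofit compare-methods --arms 3 --replicates 10 --seed 1 --out report.json
```

Curve files are plain CSV (`time_s,indentation_m,force_n` preprocessed, or
`time_s,z_m,deflection_m` raw with a spring constant in the experiment
config; see `viscofit.preprocess_io`). All outputs carry provenance
(input hashes, config hash, seed) and are bit-exact across reruns,
independent of `--jobs`.

## Python API

```python
import numpy as np
from viscofit import (ContactGeometry, FitConfig, GeneralizedMaxwell,
                      RampProtocol, fit_iterative, select_terms,
                      simulate_curve, spectrum, frequency_grid)

geom = ContactGeometry(R=12.5e-6, nu=0.5)
truth = GeneralizedMaxwell(Ge=400.0, arms=((1200.0, 1e-4), (600.0, 1e-3)))
curve = simulate_curve(truth, RampProtocol(max_force=None,
                                           max_indentation=2e-7), geom)
results = fit_iterative(curve, geom, FitConfig(max_terms=3, seed=0))
n = select_terms(results, curve, geom)
spec = spectrum(results[n - 1].model, frequency_grid(curve.duration, 50e3))
```

## Tests and acceptance

```sh
python -m pytest -q                      # full suite incl. acceptance criteria
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the package-level acceptance criteria
(exact Hertz reduction, O(n²) convolution-oracle equivalence, dual-model
physical equivalence, parameter recovery, term-count selection,
method-comparison stability, the 3/2 slope bound, frequency-band
contract, aggregation coverage, CLI determinism). The acceptance script
writes an empty JSON report — the acceptance contract is property-based,
with no numeric point targets — after running fast smoke checks.
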