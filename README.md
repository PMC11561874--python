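# atmcorr

Atmospheric-absorption correction for infrared spectra. Fluctuating water
vapor and CO₂ in a spectrometer chamber leave sharp, time-varying rotational
fine structure in background-corrected spectra. `atmcorr` removes it using
only **two sequentially measured sample spectra**: their difference isolates
the interferent lineshape, a scaling factor γ is chosen by minimizing the
point-to-point spectral length of the corrected region, and the corrected
segment is spliced back with matched endpoints.

The package also provides:

- an **RSD metric** quantifying correction efficacy across replicate series
  (per-wavenumber standard deviation normalized by a feature-free reference
  region; ≈ 1 means only noise/drift remains),
- a **synthetic FTIR scene simulator** (analyte bands + interferent line
  combs with per-scan coefficients, instrument-lineshape convolution, drift
  and noise) with exact ground-truth scaling factors for every sequential
  pair,
- a **chemometrics demo**: Savitzky–Golay second derivatives and PLS
  regression with latent-variable count selected by a PRESS/F-test rule,
  comparing corrected vs uncorrected pipelines.

## Library quick start

```python
import numpy as np
from atmcorr import (
    correct_pair, default_interferents, read_spectrum_csv, rsd_profile,
)

s1 = read_spectrum_csv("scan_000.csv", timestamp=0.0)
s2 = read_spectrum_csv("scan_001.csv", timestamp=1.0)
result = correct_pair(s1, s2, default_interferents())
print({k: v["gamma"] for k, v in result.per_interferent.items()})
corrected = result.corrected  # same axis; regions overwritten + spliced
```

The default interferent configuration covers the standard atmospheric
regions (CO₂ 600–914, 2208–2442, 3602–3627, 3701–3731; H₂O 1205–2072,
3231–4000 cm⁻¹), processed in that order. When a sharp analyte band sits
inside a correction region, set `gamma_region` on that interferent to a
clean region of the same species (e.g. estimate the water γ in 3231–4000
and apply it in 1205–2072).

Spectra are two-column CSV (wavenumber cm⁻¹, absorbance AU) or single-block
JCAMP-DX (AFFN, absorbance). A fresh background before each sequence is a
usage requirement: interferent absorption that does not change between the
two spectra cannot be corrected.

## CLI

```bash
atmcorr simulate --config scene.json --seed 1 --out sim/
atmcorr correct  --in sim/ --config interferents.json --pairing next --out corrected/
atmcorr rsd      --corrected corrected/ --uncorrected sim/ \
                 --target 1200:2100 --reference 4800:5000 --out rsd.json
atmcorr plsr     --samples samples.csv --alpha 0.25 --window 11 --polyorder 3 --out plsr.json
```

Every command writes a `manifest.json` (command line, config snapshot, seed,
SHA-256 input digests, package version) next to its outputs. `correct`
emits one corrected CSV per input pair plus a JSON sidecar with per-
interferent γ, bounds warnings and spectral lengths before/after. Under the
default `next` pairing, spectrum *k* is corrected with spectrum *k+1* and
the final spectrum is dropped.

## Module map

| Module | Contents |
| --- | --- |
| `atmcorr.spectra` | `Spectrum`, `SpectrumSeries`, `Region`, `InterferentSpec`; CSV/JCAMP-DX I/O; region slicing |
| `atmcorr.correction` | difference spectrum, point-to-point length, γ optimization, splice, pair/series drivers |
| `atmcorr.evaluation` | pointwise std and RSD profiles |
| `atmcorr.simulate` | line combs, scene configs, series simulation, resolution sweep |
| `atmcorr.chemometrics` | SG second derivative, PLS1 (NIPALS), group-CV PRESS, F-test LV selection, lipid demo |
| `atmcorr.cli` | `atmcorr` command group with run manifests |
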