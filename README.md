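# condensquant

Quantification of liquid-liquid phase separation assays and of the
sub-micron cadherin/catenin clusters that condensation nucleates at
cell-cell contacts. The package targets researchers analysing:

1. **In-vitro droplet assays** of purified condensate-forming proteins
   (e.g. β-catenin with E-cadherin's cytosolic tail and α-catenin):
   droplet segmentation and the standard enrichment metrics,
2. **Junction line profiles** of fluorescently tagged adhesion proteins:
   cluster peak calling, two-channel colocalization and Gaussian sizing,
3. **FRAP recovery** of membrane clusters: double normalisation and
   single-exponential recovery fitting.

A seeded synthetic-data generator (`condensquant.synthgen`) renders
droplet fields, junction profiles and FRAP traces from known ground
truth, so every estimator in the package is validated by parameter
recovery — no experimental data required.

## The quantities computed

**Droplet assays** — droplets are segmented by intensity, size and
circularity (4π·A/P²) thresholds. Per droplet, the *partition ratio* is

    PR = C_in / C_out

the mean fluorescence inside the droplet over the mean bulk
fluorescence. Per field, the *condensed fraction* is

    CF = TC_in / TC_out

total fluorescence inside droplets over the total fluorescence of the
field. Droplets with PR below a per-channel floor (1.1 for green/red
fluorophores, 1.35 for the blue channel, which receives green
bleedthrough) are excluded from that channel's statistics. A
*co-condensed fraction* evaluates a client channel's CF over a scaffold
channel's droplet mask, and condition tables can be normalised per
channel to a reference condition.

**Junction clusters** — 4-px-wide line profiles over cell-cell contacts
are normalised to the mean of their 20th–40th lowest intensity values;
cluster peaks are local maxima with prominence ≥ 50 % (or 25 %) of the
profile's dynamic range. Reported statistics: peaks per µm, the fraction
of reference-channel peaks with a partner-channel peak within 3 px
(undefined when a contact has no reference peaks), the squared Pearson
correlation of the paired profiles, and cluster diameters from a
Gaussian fit as FWHM = 2√(2 ln 2)·σ.

**FRAP** — background-subtracted traces are normalised so the pre-bleach
mean maps to 1 and the immediate post-bleach frame to 0, then fitted to

    Y(t) = Y(0) + (F_mob − Y(0)) · (1 − e^(−t ln2 / τ½))

yielding the mobile fraction F_mob and recovery half-time τ½; the
recovered plateau is compared to an unbleached reference region of the
junction on the same intensity scale.

## Worked example

```python
import numpy as np
from condensquant import synthgen, frapkinetics as fk

norms = []
for seed in range(200):
    truth = synthgen.FrapTruth(y0=0.0, f_mob=0.7, tau_half_s=17.0,
                               interval_s=10.0, duration_s=300.0,
                               noise_sd=0.05, seed=seed)
    frame, _ = synthgen.gen_frap_trace(truth)
    norms.append(fk.normalize_frap(fk.FrapTrace.from_frame(frame)))
fit = fk.fit_recovery(norms, "ensemble-mean")
print(f"F_mob = {fit.f_mob:.3f}, tau_half = {fit.tau_half_s:.2f} s")
```

prints

```
F_mob = 0.700, tau_half = 17.03 s
```

i.e. fitting the pointwise mean of 200 noisy simulated traces recovers
the generative mobile fraction (0.7) and recovery half-time (17 s) of a
dynamic membrane cluster. The same workflow is available from the shell:

```bash
condensquant simulate --kind frap --seed 2 --out sim/
condensquant frap --traces sim/trace.csv --out fit/ --mode per-trace
# -> F_mob = 0.700, tau_half = 17.0 s
```

`condensquant {simulate, droplets, junction, frap, report}` covers the
synthetic generators, the three analysis pipelines, and replicate-aware
summaries of manually scored de-novo junction-formation experiments.

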