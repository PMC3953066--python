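# seednmr

Low-field (time-domain) NMR T2 relaxometry of seed water compartments.

Water inside a plant seed is not one pool. During imbibition of an
*Arabidopsis* seed, protons report from the solid phase (macromolecules),
from exchangeable hydroxyl protons, from water mixed with oil inside the
tissues, from water held in the adherent mucilage layer around the seed
coat, and from free water outside the seed. Each pool has a distinct
spin-spin relaxation time T2, so the transverse relaxation decay measured on
a benchtop 20 MHz spectrometer is a sum of exponentials:

    I(t) = Σᵢ Aᵢ · exp(−t / T2ᵢ)

with amplitudes Aᵢ (percent of the extrapolated t→0 signal) and relaxation
times T2ᵢ spanning 0.016 ms (solid) to ~500 ms (external water). `seednmr`
implements the full analysis chain used to quantify these pools and their
dynamics:

* **Joint FID + CPMG discrete fitting** — the free induction decay (0.4 µs
  dwell) is the only window onto the solid phase, while the CPMG echo train
  (0.2 ms echo, thousands of echoes) resolves the mobile pools; both curves
  are fitted together with one shared amplitude scale, by
  variable-projection nonlinear least squares with Aᵢ ≥ 0 enforced exactly.
  The number of components is chosen by a nested F-test (or BIC).
* **Regularized T2-spectrum inversion** (maximum entropy or Tikhonov, with
  discrepancy-principle regularization) as the model-free cross-check of the
  discrete fit.
* **Compartment analysis** — attribution of components by T2 rank, oil
  content of dry seeds from A(3)+A(4), per-compartment water contents via a
  distilled-water calibration with the oil signal subtracted, and
  mono-exponential water-transfer kinetics A(t) = A∞ + (A₀ − A∞)·e^(−t/τ).
* **A synthetic decay generator** reproducing the published component sets
  for wild-type and mucilage-mutant (*mum2-11*, *myb5-1*) seeds, so every
  stage is testable without instrument data.

The package is written for seed physiologists and NMR relaxometry users who
want a scripted, reproducible version of this analysis, in the
statsmodels style: a model object built from data whose `fit()` returns a
results object with estimates, standard errors and a `summary()`.

## Worked example

Simulate a realistic noisy acquisition of a dry wild-type seed sample,
let the F-test choose the number of components, and read off the oil
content:

```python
from seednmr import (AcquisitionConfig, MultiExponentialModel, NoiseModel,
                     assign_compartments, estimate_oil, reference_set,
                     simulate_decay)

dry = reference_set("wt-dry")
curves = [simulate_decay(dry, AcquisitionConfig.fid(),  NoiseModel(0.2, 0)),
          simulate_decay(dry, AcquisitionConfig.cpmg(), NoiseModel(0.2, 1))]
res = MultiExponentialModel(curves).fit_select()
res.components = assign_compartments(res, "dry")
print(res.summary())
print("oil content:", round(estimate_oil(res), 1), "% of dry signal")
```

```
Discrete multi-exponential fit
==============================================================
components: 4    observations: 8150
rss: 323.657    dof: 8142    converged: True
extrapolated t->0 amplitude: 99.9315
--------------------------------------------------------------
 component                   label  amplitude_pct  amplitude_se    t2_ms      t2_se
         1                   solid         49.197        0.1407 0.016497 8.1078e-05
         2            exchangeable         11.402       0.14661  0.23957   0.010152
         3 oil_intracellular_water         20.277       0.09342   35.301    0.21566
         4      oil_mucilage_water         19.124        0.1027   138.38    0.44374
...
oil content: 39.4 % of dry signal
```

The four pools of a dry seed come back at their generating values (solid
49.1 % at 0.0164 ms, exchangeable 11.5 % at 0.23 ms, and the two oil
components whose summed amplitude, 39.4 %, is the oil content), each with a
standard error of ~0.1–0.15 amplitude-points at this noise level.

Partitioning water for an imbibed sample needs a dry reference (it anchors
the absolute scale and supplies the oil signal). On a fully-bookkept
synthetic seed — 210 mg of seeds, 17 mg bound water, oil at 40 % of the dry
signal, then 15/60/70/40 mg of water added to the exchangeable,
intracellular, mucilage and external pools:

```python
from seednmr import partition_water, synthetic_seed_sample

dry_fit, imb_fit, meta, calib, truth = synthetic_seed_sample(
    seed_mass_mg=210.0, bound_water_mg=17.0, oil_signal_fraction=0.40,
    water_added_mg={"exchangeable": 15.0, "oil_intracellular_water": 60.0,
                    "oil_mucilage_water": 70.0, "external_water": 40.0})
print(partition_water(imb_fit, dry_fit, meta, calib).summary())
```

```
Water partition
==============================================================
 component                   label  amplitude_pct  t2_ms  water_pct  oil_signal_abs
         1                   solid          21.71 0.0249          0               0
         2            exchangeable          9.572  2.466      8.101               0
         3 oil_intracellular_water          27.11   19.8      15.19           30.62
         4      oil_mucilage_water          29.64    114      17.72            29.1
         5          external_water          11.97    457      10.13               0
--------------------------------------------------------------
oil (dry signal): 40 %   split 3:4 = 0.513:0.487
total water: 51.14 % w/w   external fraction: 0.545
```

Every recovered water percentage equals its ground truth (e.g. the
adherent-mucilage pool: 70 mg / 412 mg total mass = 17.72 % w/w), the oil
signal is conserved, and over half of the water sits outside the seed
tissues — the mucilage-trapping effect that keeps mutant seeds buoyant
shows up directly in `external_fraction`.

A command-line interface wraps the same library
(`seednmr simulate|fit|invert|partition|kinetics|report`); `seednmr report
config.yaml` runs the whole chain from one YAML file and logs every default
it used.

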