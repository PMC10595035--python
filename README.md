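# needlesense

Bio-impedance tissue identification toolkit for simulated robot-assisted
needle insertion (lumbar puncture / epidural steroid injection):

* **`needlesense.remap`** — saline-calibrated remapping of 15-point impedance
  spectra (|Z| in Ω at 1–349 kHz) to conductivity spectra (µS/cm), the
  classifier's 15 features. Ships a default calibration table (8 saline
  baths × 15 frequencies) built from per-bath median impedances.
* **`needlesense.bnn`** — variational Bayesian neural-network classifier
  (15-10-10-4, Gaussian weight posteriors under a standard-normal prior,
  cost = cross-entropy + KL/batch_size, 2,000 full-batch epochs). Pure
  numpy: reparameterized sampling, manual backprop, hand-rolled Adam,
  analytic Gaussian–Gaussian KL. Prediction averages the softmax over
  posterior draws and reports the spread of the winning class probability
  as a confidence measure.
* **`needlesense.phantom`** — synthetic layered-tissue phantom: log-normal
  impedance templates per tissue class (skin, fat, ligament, CSF), labeled
  dataset generation with the reference class balance (150/81/149/146),
  and depth-indexed spectra with log-linear blending at layer interfaces.
* **`needlesense.control`** — closed-loop insertion state machine
  (advance one motor step → measure → remap → classify → stop-on-target),
  stop policies with debouncing and an arming rule (epidural injections stop
  in fat only after ligament has been seen, so subcutaneous fat never
  triggers), and comfortable-travel-distance bookkeeping
  Δ = (N₂ − N₁)·Hs with the motor step Hs ∈ [0.08, 0.22] mm.
* **`needlesense.io_cli`** — CSV/JSON readers and writers (calibration
  table, wide datasets, single spectra, versioned model archive, stack and
  policy configs, detection log) and the command-line interface.

## CLI

```sh
needlesense generate --out dataset.csv --seed 1          # synthetic dataset
needlesense train --dataset dataset.csv --out model.json # fit the BNN
needlesense classify --model model.json --spectrum spec.csv
needlesense simulate --model model.json --seed 4 --log run.csv
needlesense simulate --oracle --target fat               # perfect classifier
needlesense calibrate saline.csv --out table.csv         # rebuild the table
```

All subcommands accept `--seed`; every error path exits non-zero with a
one-line cause. `needlesense --help` lists global flags.

## Notes

* The toolkit treats the analyzer output as impedance *magnitude* |Z|;
  phase/real-part decomposition is out of scope.
* Remapping clamps out-of-range impedances to the nearest calibration node
  and flags them (`ConductivitySpectrum.out_of_range`) rather than
  extrapolating silently.
* Conductivity features are standardized internally before the first layer
  (per-feature mean/std stored in the model archive); disable with
  `BNNConfig(standardize=False)`.
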