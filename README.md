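# dcmnet

Effective-connectivity analysis of a 7-region action-representation network
(OP, MT/V5, pSTS, aIPS, IPL, PMv, S/M1), exercised end to end on synthetic
data:

- **design** — block design (9 rest + 8 task epochs of 24 s, TR 3 s, 6 runs,
  136 volumes/run, 798 retained), three boxcar inputs (task, execution,
  hand observation) at microtime resolution, and the per-volume 600-ms
  gradient-silent windows used for EMG.
- **generative** — bilinear neural state equation
  `dz/dt = (A + Σ u_j B_j) z + C u` coupled to a balloon hemodynamic model,
  integrated with RK4 at microtime and sampled at the TR.  A compiled
  (numba) kernel also propagates forward sensitivities for fast Jacobians.
- **model_space** — the 23-edge baseline graph and the 16 candidate models
  (4 PMv↔pSTS connection patterns × 4 direct-input patterns), plus the two
  orthogonal 4-family partitions.
- **inversion** — variational-Laplace estimation of the coupling
  parameters: Gauss–Newton with Levenberg–Marquardt trial steps, EM updates
  of per-region noise precision with graduated precision annealing,
  Gaussian shrinkage priors, DCT high-pass confound projection, and a
  Laplace free-energy evidence approximation.
- **bms** — random-effects Bayesian model selection (Dirichlet posterior by
  digamma fixed point), Monte-Carlo exceedance probabilities, family-level
  inference with rebalanced priors.
- **group_stats** — one-sample/paired t tables per connection with
  Benjamini–Hochberg FDR.
- **synthetic** — group generator: published group-mean couplings as the
  population truth on the dual-input mutual-connection model, Gaussian
  between-subject variation with stability screening, per-region SNR noise,
  plus synthetic EMG with execution/mimicry bursts.
- **emg** — silent-window rectification/integration, within-subject
  z-normalization, per-condition task-minus-rest summaries.
- **coords** — Talairach↔MNI (piecewise Brett affine), coordinate
  averaging, nearest-peak selection.
- **pipeline / cli** — configuration-driven orchestration:
  simulate → invert → BMS/families → group tables → report.

## CLI

```sh
dcmnet run-all --config study.yaml --seed 1 --out study_out
dcmnet simulate --seed 1 --out study_out --subjects 4
dcmnet coords --input peaks.csv --to mni --out peaks_mni.csv
dcmnet emg --trace emg.tsv --session study_out/session.json --out emg.csv
```

`study.yaml` holds `StudyConfig` fields (`n_subjects`, `n_runs`, `snr`,
`model_ids`, inversion options, `seed`, `out_dir`, ...); command-line flags
override it.  Reports, evidence matrices and connection tables are written
as JSON/CSV with seeds and a config hash recorded.

## Notes on the heavy acceptance tests

`tests/test_acceptance.py` criteria 6–7 run genuine inversion studies at
reduced scale (single-run sessions, small groups).  Parameter recovery is
information-limited at the specified noise level: an oracle estimator
linearized at the true parameters attains a pooled truth–posterior
correlation of only ≈0.59 (133 volumes) to ≈0.68 (798 volumes), so the 0.7
acceptance threshold cannot be met by any faithful estimator at that SNR;
the test asserts the specified level regardless and is expected to fail,
documenting the measured value.
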