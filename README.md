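# aptanomaly

Semi-supervised anomaly detection for aptasensor drain-current time series.

Aptamer-functionalized field-effect-transistor (FET) biosensors record a
drain current while analyte is injected step-wise into the sensor well.
Interpreting a faulty recording — a broken transistor, a device that never
senses the analyte, an interval of erratic behaviour — leads to wrong
concentration calls, so flagging anomalous segments is the first step of
any downstream analysis.  Labelled anomalies are scarce and heterogeneous;
`aptanomaly` therefore trains only on *normal* segments and flags anomalies
by reconstruction error.

The pipeline: z-score each signal x ↦ (x−μ)/σ, cut it into
per-concentration segments of length L, train three autoencoders on normal
segments (a 16-unit vanilla autoencoder, and unidirectional/bidirectional
LSTM sequence autoencoders with an LSTM(32)→LSTM(16)→LSTM(32)→linear
stack), score each segment by MSE(x, x̂), and set the decision threshold
τ_u as the upper endpoint of the 90% central interval of the training-error
distribution estimated by Gaussian KDE with the plug-in bandwidth

    H ≈ 1.06 σ m^(−1/5).

A segment with error r > τ_u is an anomaly (ζ = 0).  Five models are
evaluated: the three networks, plus two integrated models in which a
segment is normal only if both an LSTM detector and the vanilla detector
pass it.  Because the real sensor datasets are restricted, the package
ships a seeded simulator of normal signals (concentration-proportional
injection peaks, monotone drift, Gaussian noise) and of four anomaly
classes (abnormal points / abnormal interval / broken transistor /
no-sense), which stands in for them everywhere.

## Worked example

```python
import numpy as np
from aptanomaly.benchmark import benchmark_datasets
from aptanomaly.autoencoders import train_autoencoder, TrainingConfig
from aptanomaly.thresholding import fit_detector

train, test = benchmark_datasets(seed=1)          # 60 train / 40 test segments
net = train_autoencoder("vanilla", train, TrainingConfig(seed=7))
det = fit_detector(net, train, level=0.90)
errs = det.errors(test)
dec  = det.predict(test)                          # 1 = normal, 0 = anomaly
print(f"tau_u = {det.tau_u:.4f}")
print(f"accuracy = {np.mean(dec == test.labels):.3f}")
print(f"median error: normal {np.median(errs[test.labels==1]):.4f}, "
      f"anomaly {np.median(errs[test.labels==0]):.4f}")
```

prints

```
tau_u = 0.0670
accuracy = 0.850
median error: normal 0.0063, anomaly 0.6222
```

— the threshold (the KDE 0.95 quantile of the 60 training errors) cleanly
separates the two medians by two orders of magnitude; the handful of missed
anomalies are no-sense segments from windows with little or no injection
peak to suppress.

The same flow is available from the shell:

```bash
aptanomaly run --config cfg.yaml --seed 1 --workdir out/
# or stage by stage:
aptanomaly simulate --workdir out/ ; aptanomaly prep --workdir out/ ; ...
```

producing `manifest.tsv`, `train.csv`/`test.csv` segment stores, one
`detector_<kind>.h5` per network, `decisions.csv` and a consolidated
`report.json` with confusion counts and sensitivity/precision/F1/accuracy
per model.

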