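"""Generate a synthetic multi-origin herb fingerprint batch set.

Emulates the study conditions of the raw-herb quality screen: 15 batches
(3 origins x 5 batches) with 11 shared chromatographic peaks, origin-level
archetype area profiles, 5% multiplicative batch noise and 0.01 min RT
jitter.  Writes the pooled peak table and the ground-truth origin labels.
"""

import json
from pathlib import Path

from herbqc.fingerprint import write_peak_tables
from herbqc.synthetic import SynthConfig, make_fingerprints

OUT = Path("results")
OUT.mkdir(exist_ok=True)

cfg = SynthConfig(seed=42, n_origins=3, batches_per_origin=5, n_peaks=11,
                  rt_jitter_sd=0.01, area_noise_cv=0.05, dropout_prob=0.0)
tables, labels = make_fingerprints(cfg)

write_peak_tables(tables, OUT / "synthetic_peaks.csv")
truth = {t.sample_id: lab for t, lab in zip(tables, labels)}
(OUT / "synthetic_peaks.truth.json").write_text(json.dumps(truth, indent=2))

print(f"wrote {len(tables)} batch peak tables "
      f"({cfg.n_origins} origins x {cfg.batches_per_origin} batches, "
      f"{cfg.n_peaks} peaks) to {OUT/'synthetic_peaks.csv'}")
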