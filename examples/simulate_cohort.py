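"""Generate a small synthetic PSG cohort and summarize it.

Each record bundle is an EDF signal file (2 EEG, 2 EOG, 1 chin-EMG
channel at 200 Hz), an arousal-event TSV, a hypnogram, and a row in the
cohort metadata table.  The printed arousal indices should scatter
around the configured target rate.
"""

import tempfile
from pathlib import Path

import numpy as np

from arousalkit import arousal_index, read_events, read_hypnogram, read_metadata_table
from arousalkit.synth import SynthConfig, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    cfg = SynthConfig(n_records=5, duration_s=2 * 3600.0, target_ari=25.0, seed=1)
    ids = generate_cohort(cfg, tmp)
    metas = read_metadata_table(Path(tmp) / "metadata.csv")
    print(f"cohort of {len(ids)} records, 2 h each, target ArI 25/h")
    for rid in ids:
        events = read_events(Path(tmp) / f"{rid}.events.tsv")
        hyp = read_hypnogram(Path(tmp) / f"{rid}.hyp.txt")
        m = metas[rid]
        print(
            f"  {rid}: {len(events):3d} arousals, "
            f"TST {hyp.total_sleep_time_s() / 60:5.1f} min, "
            f"ArI {arousal_index(events, hyp):5.1f}/h, "
            f"age {m.age}, sex {m.sex}, groups {sorted(m.diagnosis_groups)}"
        )

# The ArI column is the clinically reported rate: arousals per hour of
# sleep (non-wake hypnogram time), not per hour of recording.
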