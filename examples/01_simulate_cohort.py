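"""Generate a small synthetic neonatal-like EEG cohort and inspect it.

Builds three 4-minute, 9-channel recordings with annotated rhythmic
seizure discharges on a 1/f background, and prints per-recording summary
lines.  The per-patient amplitude factors differ — this inter-patient
baseline shift is exactly what feature baseline correction later removes.
"""

import numpy as np

import seizurekit as sk
from seizurekit.synthetic import patient_amplitude_factor

config = sk.neonatal_config(n_patients=3, duration_s=240, seed=11,
                            seizure_rate=1.0, seizure_duration_s=(20, 40))
recordings = sk.generate_cohort(config)

for rec in recordings:
    idx = int(rec.patient_id.split("P")[-1])
    factor = patient_amplitude_factor(config, idx)
    rms = np.sqrt(np.mean(rec.signal**2))
    spans = ", ".join(f"[{s:.0f}, {e:.0f}) s" for s, e in rec.annotations)
    print(f"{rec.patient_id}: {rec.signal.shape[0]} channels, "
          f"{rec.duration_s:.0f} s, RMS {rms:.1f} uV "
          f"(patient amplitude factor {factor:.2f}), seizures at {spans}")

# The RMS scales with the patient factor: patients are not interchangeable
# without baseline correction.
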