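"""Simulate a two-class oscillatory cohort and inspect one recording.

Builds a small cohort with a phase effect in the theta band (the ASD
class's preferred phase angle leads the TD one by pi/2), then prints the
band power and theta preferred phase angle of an affected channel for one
subject of each class.
"""

import numpy as np

from ppafuse import (
    DEFAULT_BANDS,
    band_psd_features,
    fft_phases,
    generate_cohort,
    preferred_phase_angle,
    preset_specs,
    welch_spectrum,
)

spec_td, spec_asd = preset_specs("phase-only")
cohort = generate_cohort(3, spec_td, spec_asd, duration=30.0, fs=250.0, seed=42)

for rec in (cohort.recordings[0], cohort.recordings[-1]):  # one TD, one ASD
    psd = band_psd_features(welch_spectrum(rec))[0]  # channel 0 (affected)
    phases = fft_phases(rec).phase[0]
    ppa, consistency = preferred_phase_angle(phases, band=(4, 8))
    print(f"subject {rec.subject_id} ({rec.label}):")
    for name, value in zip(DEFAULT_BANDS.names, psd):
        print(f"  PSD_{name:<10} {value:7.2f} dB")
    print(f"  PPA_theta  {ppa:+.2f} rad  (consistency {consistency:.2f})")

print()
print("The theta band carries tones in both classes (similar PSD_theta),")
print("but the ASD subject's preferred theta phase sits near +pi/2 = +1.57")
print("while the TD subject's sits near 0 - the phase feature, not the")
print("power feature, separates the classes here.")
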