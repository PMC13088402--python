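"""Regenerate the frozen acoustic-model constants.

Measures, from the bruit simulator and the default scoring chain:

* ``SURROGATE_K0`` - band power of unit-amplitude, flat-envelope
  turbulence noise (FV = 1000 mL/min, RI = 0, no measurement noise);
* ``SURROGATE_STENOSIS_FACTOR`` - band-power ratio with the stenotic
  spectral shift, same conditions;

then derives the default calibration (p_min, p_max) so that the default
scenario spans roughly [41, 999] over the observed verification flow
range 160-3025 mL/min (score 41 at FV = 160 / RI = 0.75; score 999 at
FV = 3025 / RI = 0.39).

Run from the repository root:  python scripts/tune_calibration.py
The printed values are the ones frozen in hvsi.bruitsim / hvsi.signal_core.
"""

import numpy as np

from hvsi import signal_core
from hvsi.bruitsim import BruitScenario, envelope_rms, simulate_bruit
from hvsi.signal_core import (
    AudioSignal,
    apply_band_filters,
    band_power,
    compute_spectrogram,
)

N_SEEDS = 40


def measured_power(scenario: BruitScenario) -> float:
    sig = simulate_bruit(scenario)
    x, fs = signal_core._resample(sig.samples, sig.sampling_rate, 4000)
    x = signal_core._analysis_segment(x, fs, 5.0, 0.25)
    return band_power(apply_band_filters(compute_spectrogram(AudioSignal(x, fs))))


def main() -> None:
    flat = [
        measured_power(
            BruitScenario(flow_volume=1000, resistance_index=0.0, noise_level=0.0, seed=s)
        )
        for s in range(N_SEEDS)
    ]
    k0 = float(np.mean(flat))
    sten = [
        measured_power(
            BruitScenario(
                flow_volume=1000, resistance_index=0.0, noise_level=0.0,
                seed=s, stenosis_present=True,
            )
        )
        for s in range(N_SEEDS)
    ]
    sten_factor = float(np.mean(sten)) / k0
    print(f"SURROGATE_K0 = {k0:.1f}")
    print(f"SURROGATE_STENOSIS_FACTOR = {sten_factor:.3f}")

    # Calibration: anchor score 999 at (FV 3025, RI 0.39) and score 41 at
    # (FV 160, RI 0.75) using the surrogate's closed-form envelope factor.
    p_max = 3.025 * envelope_rms(0.39) * k0
    p_160 = 0.160 * envelope_rms(0.75) * k0
    decades = np.log10(p_max / p_160) / (1.0 - 41.0 / 999.0)
    p_min = p_max / 10**decades
    print(f"calibration p_min = {p_min:.1f}  (frozen: 657.0)")
    print(f"calibration p_max = {p_max:.1f}  (frozen: 22800.0)")


if __name__ == "__main__":
    main()
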