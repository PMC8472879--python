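"""Independent brute-force oracles used by the test suite."""

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq


def brute_force_snr(window, fs):
    """Periodogram band-summation oracle for the spectral SNR measure."""
    window = np.asarray(window, dtype=float)
    n = len(window)
    nfft = next_fast_len(max(n, int(np.ceil(fs / 0.02))))
    power = np.abs(rfft(window - window.mean(), nfft)) ** 2
    freqs = rfftfreq(nfft, 1.0 / fs)
    hr_band = (freqs >= 0.5) & (freqs <= 3.0)
    f0 = freqs[hr_band][np.argmax(power[hr_band])]
    analysis = (freqs >= 0.5) & (freqs <= min(8.0, fs / 2))
    e_p = e_s = 0.0
    for f, p in zip(freqs[analysis], power[analysis]):
        if abs(f - f0) <= 0.2 or abs(f - 2 * f0) <= 0.2:
            e_p += p
        else:
            e_s += p
    return 10.0 * np.log10(e_p / e_s)
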