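"""Burg autoregressive spectrum of a short quasi-periodic segment.

Fits AR models over orders 10-50 to one standardized 5-s segment, selects
the order by AIC, evaluates the parametric power spectral density, and
compares the spectral peak with a zero-padded periodogram of the same
segment.  Burg spectra stay smooth and sharply peaked even on segments
this short, which is why the method suits 5-s physiological windows.
"""

import numpy as np
from scipy import signal as ss

import gillwave as gw
from gillwave.conditioning import VENTILATORY_FILTER, bandpass, segment_signal, standardize

rec, truth = gw.gen_ventilatory(
    gw.VentilatorySimSpec(mean_freq_hz=2.8, interval_cv=0.05, noise_sd=0.05,
                          duration_s=10.0, seed=4)
)
x = bandpass(rec.samples[0], rec.rate_hz, VENTILATORY_FILTER)
z = standardize(segment_signal(x, rec.rate_hz)[1])

best_p, model = gw.select_order_aic(z.values, rec.rate_hz)
psd = gw.ar_psd(model, n_freq=901, band=(1.0, 10.0))
peak = gw.peak_frequency(psd)

f, p = ss.periodogram(z.values, fs=rec.rate_hz, nfft=2**16)
band = (f >= 1) & (f <= 10)
peak_pgram = f[band][np.argmax(p[band])]

print(f"true rhythm:            {truth['mean_freq_hz']:.2f} Hz")
print(f"AIC-selected AR order:  {best_p} (scanned 10..50)")
print(f"residual variance:      {model.residual_variance:.2e}")
print(f"AR spectral peak:       {peak:.2f} Hz")
print(f"periodogram peak:       {peak_pgram:.2f} Hz")
print()
print("The two estimators agree within the grid resolution on narrowband")
print("segments; the AR peak is the ventilatory frequency index.")
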