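"""Estimate the basal actomyosin oscillation period of a noisy, bleaching
cell, two ways.

Builds one synthetic 30-minute intensity trace (true period 180 s, 30 s
frames, 30% noise, photobleaching with tau = 900 s), corrects the
bleaching, and compares the peak-interval and autocorrelation period
estimates with the known truth.
"""

import numpy as np

from oscillaquant import synth, traces

truth = synth.TraceGroundTruth(
    true_period=180.0,          # s
    amplitude=300.0,            # AFU
    baseline=600.0,             # AFU
    bleach_time_constant=900.0, # s
    noise_sd=90.0,              # 30% of the amplitude
    seed=11,
)
real = synth.make_oscillatory_trace(truth, duration=1800.0, dt=30.0)

corrected = traces.correct_photobleaching(real.trace)

peaks = traces.detect_peaks(corrected)
intervals = traces.peak_interval_periods(peaks)
acf_est = traces.autocorrelation_period(corrected)

print(f"true period:            {truth.true_period:.0f} s")
print(f"peak-interval estimate: {intervals.mean_period:.0f} s "
      f"({len(intervals.intervals)} intervals, sd {intervals.sd:.0f} s)")
print(f"autocorrelation:        {acf_est.period:.0f} s "
      f"(detectability {acf_est.detectability_score:.2f}, "
      f"{acf_est.n_cycles_observed} cycles)")
print(f"per-cycle mean intensity: "
      f"{np.mean(traces.cycle_mean_intensity(corrected, acf_est)):.0f} AFU")

# Both estimates should sit within one frame (30 s) of the truth; the
# detectability score is the autocorrelation value at the reported lag —
# a white-noise trace would be reported NOT_PROMINENT instead.
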