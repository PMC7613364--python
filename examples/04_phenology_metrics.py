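"""Extract crop phenology indicators from a reconstructed LAI series.

Reconstructs a two-year corn-like pixel and reports, per detected growing
season: start/end of season (20% of the seasonal amplitude above the base
level), day of maximum, length of season, amplitude, and the seasonal
integrals between SOS and EOS (blue: above zero; green: above base level).
"""

import numpy as np

import phenofill as pf
from phenofill.synthetic import CropCurveParams, double_logistic

rng = np.random.default_rng(5)
corn = CropCurveParams(base=0.25, amplitude=3.6, sos_true=160, eos_true=290,
                       growth_rate=0.11, senescence_rate=0.10)
times = np.sort(rng.uniform(0, 730, 120))
y = double_logistic(times, corn, years=2) + rng.normal(0, 0.1, times.size)
ts = pf.TimeSeries(times, y)

theta, _ = pf.train_hyperparameters(ts, seed=0)
grid = np.arange(times[0], times[-1], 5.0)
series = pf.reconstruct_pixel(ts, theta, grid)

print("detected seasons (days counted from the epoch, 1 Jan of year 1):")
for k, m in enumerate(pf.extract_pixel_phenology(series)):
    print(f"\nseason {k + 1}:")
    print(f"  SOS = {m.sos:6.1f} d   EOS = {m.eos:6.1f} d   "
          f"LOS = {m.los:5.1f} d")
    print(f"  DOM = {m.dom:6.1f} d   max = {m.max_value:.2f} LAI   "
          f"amplitude = {m.amplitude:.2f} LAI")
    print(f"  blue area = {m.blue_area:6.1f} LAI*d   "
          f"green area = {m.green_area:6.1f} LAI*d")
print(f"\ngenerating truth: SOS {corn.sos_true} / EOS {corn.eos_true} "
      f"(+365 for year 2); the extracted\ndates land within a few days — "
      f"the residual comes from observation noise and the\n5-day grid.")
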