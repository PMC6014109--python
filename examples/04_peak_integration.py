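"""Render SRM chromatograms and integrate them back to peak areas.

The simulator can emit Gaussian elution profiles whose integrals equal the
programmed transition areas; the integration stage recovers area and apex
retention time and verifies natural/heavy co-elution.
"""

import pandas as pd

from seedmrm import quant, simdata

records = pd.DataFrame(
    [
        {"peptide": "FVYASVLR", "transition": "T1", "channel": "natural",
         "area": 52_000.0},
        {"peptide": "FVYASVLR", "transition": "T1", "channel": "heavy",
         "area": 180_000.0},
    ]
)
traces = simdata.render_chromatograms(records, baseline_noise=25.0, seed=3)

apexes = {}
for rec, trace in zip(records.itertuples(), traces):
    window = (trace.times[0], trace.times[-1])
    area, apex = quant.integrate_peak(trace.times, trace.intensities, window)
    apexes[rec.channel] = apex
    err = 100 * (area - rec.area) / rec.area
    print(
        f"{rec.channel:7s} channel: integrated area = {area:9.0f} counts "
        f"(programmed {rec.area:.0f}, {err:+.2f}%), apex at {apex:.2f} min"
    )

coelute = quant.match_channels(apexes["natural"], apexes["heavy"], tolerance=0.2)
print(f"co-elution within 0.2 min: {coelute}")
# Matching retention times between the endogenous peptide and its heavy
# standard is the identity check that makes an SRM detection trustworthy;
# the area ratio natural/heavy (~0.29 here) is the abundance readout.
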