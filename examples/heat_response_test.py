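"""Simulate one heat-response-test visit and reduce it to scalar summaries.

Generates a noiseless 45-min walk in 40 degC / 30% RH from the deterministic
visit template, then summarizes resting values, the rise in core temperature
and end-exercise values.
"""

from heatadapt.synthetic import HRTGroundTruth, generate_hrt_series
from heatadapt.thermometry import summarize_visit

truth = HRTGroundTruth(noise_sd={"tgi": 0.0, "tsk": 0.0, "hr": 0.0, "lsr": 0.0})
series = generate_hrt_series(truth, seed=1)
vs = summarize_visit(series)

print(f"resting Tgi     {vs.resting_tgi_c:6.2f} degC   (template baseline 37.28)")
print(f"end-exercise Tgi{vs.end_tgi_c:6.2f} degC   (baseline + 1.78 rise)")
print(f"rise in Tgi     {vs.rise_tgi_c:6.2f} degC")
print(f"mean exercising Tsk {vs.mean_tsk_exercise_c:5.2f} degC")
print(f"safety stop: {vs.safety_stop}")
# The rise in Tgi is the thermal-strain outcome contrasted pre/post summer;
# a smaller rise after summer indicates heat acclimatization.
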