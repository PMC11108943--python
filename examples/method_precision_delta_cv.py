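"""Compare the replicate-to-replicate precision of ramp (RACiR) and
steady-state curve fitting with the ΔCV statistic.

ΔCV = 1 - CV_RACiR / CV_SS for a fitted parameter; positive means the
ramp method gives the tighter estimates.  Computed two ways: from
replicate synthetic fits, and from published-style mean +/- SE
summaries.
"""

from cutigas import FvCBParams, NoiseSpec, delta_cv, delta_cv_from_summary, fit_aci, recompute_curve
from cutigas.synthetic import ProtocolSpec, StomatalModel, generate_curve

truth = FvCBParams(vcmax=100.0, j=150.0, tpu=11.0, rd=1.5)
leaf = StomatalModel.static(0.16, 0.0)
noise = NoiseSpec(sd_glw=0.00415, sd_a=0.3)

fits_racir, fits_ss = [], []
for rep in range(5):
    ramp = generate_curve(ProtocolSpec.racir(start=100, end=2000), params=truth,
                          stomata=leaf, noise=noise, seed=100 + rep)
    fits_racir.append(fit_aci(recompute_curve(ramp, 0.0, "uncorrected")))
    ss = generate_curve(ProtocolSpec.steady_state(), params=truth,
                        stomata=leaf, noise=noise, seed=200 + rep)
    fits_ss.append(fit_aci(recompute_curve(ss, 0.0, "uncorrected")))

for param in ("vcmax", "j", "rd"):
    print(f"ΔCV({param}) over 5 replicates each = {delta_cv(fits_racir, fits_ss, param):+.2f}")

# and from a published-style summary (mean +/- SE, n = 5 per arm):
print(f"ΔCV from summary pairs (590.93±13.20 vs 570.88±57.83) = "
      f"{delta_cv_from_summary(590.93, 13.20, 570.88, 57.83):+.2f}")
print("Positive values: the 270-600-point ramp averages instrument noise")
print("away far better than 16 steady-state points can.")
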