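"""Generate a noisy steady-state A/C_i curve for a low-conductance
leaf and fit FvCB parameters with and without the cuticular
correction.

The corrected refit recovers a higher V_cmax: the instrument's C_i was
inflated, so the same assimilation implies more carboxylation capacity
than the uncorrected curve suggests.
"""

from cutigas import FvCBParams, NoiseSpec, fit_aci, recompute_curve
from cutigas.synthetic import ProtocolSpec, StomatalModel, generate_curve

truth = FvCBParams(vcmax=100.0, j=150.0, tpu=11.0, rd=1.5)
g_cw = 0.0056
leaf = StomatalModel.static(0.045, g_cw)  # g_lw ~ 0.05: ratio ~ 0.11

records = generate_curve(
    ProtocolSpec.steady_state(), params=truth, stomata=leaf,
    noise=NoiseSpec(sd_glw=0.00415, sd_a=0.2), seed=42,
)

for mode in ("uncorrected", "corrected"):
    fit = fit_aci(recompute_curve(records, g_cw, mode))
    tpu = f"{fit.tpu:.2f}" if fit.tpu is not None else "absent"
    print(f"{mode:>11}: Vcmax={fit.vcmax:7.2f}  J={fit.j:7.2f}  "
          f"TPU={tpu}  Rd={fit.rd:.2f}  Citrans1={fit.ci_trans1:.0f}")

print(f"\ntruth: Vcmax={truth.vcmax}, J={truth.j}, TPU={truth.tpu}, Rd={truth.rd}")
print("The corrected fit sits closer to the generating truth because the")
print("correction removes the upward C_i bias from cuticular water loss.")
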