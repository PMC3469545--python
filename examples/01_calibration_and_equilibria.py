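"""Derive the rate constants from observable quantities and inspect the
equilibrium structure of the deterministic system.

The calibration: nicotine half-life 1.8 h, craving fading to 10% after
26 days (16 waking hours each), and a moderate smoker (0.8 cigarettes/h,
1.7 mg each, 25% absorbed) sitting at equilibrium craving C = 0.5.
"""

from smokesim import (
    ModelParams,
    derive_rate_constants,
    equilibrium_craving_from_intake,
    find_equilibria,
)

params = derive_rate_constants(
    nicotine_half_life_h=1.8,
    craving_ref_days=26,
    craving_residual_fraction=0.1,
    cigs_per_hour=0.8,
    mg_per_cig=1.7,
    uptake_fraction=0.25,
    reference_C=0.5,
)
print("derived rate constants:")
print(f"  f = {params.f:.3f} mg/h   (intake gain)")
print(f"  r = {params.r:.3f} /h     (nicotine decay, half-life 1.8 h)")
print(f"  b = {params.b:.3g} /(mg h) (craving activation)")
print(f"  v = {params.v:.3g} /h     (craving decay, ~months)")

for S in (0.05, 0.1, -0.03):
    eqs = find_equilibria(S, ModelParams())
    print(f"\nequilibria at control S = {S}:")
    for eq in eqs:
        print(f"  N = {eq.N:6.3f} mg, C = {eq.C:6.3f}  [{eq.stability}]")

# At S = 0.05 the system is bistable: a steady smoker (C ~ 0.435,
# intake 0.262 mg/h) and a non-smoker (origin) coexist; the unstable
# point between them is the tipping craving level for relapse.
smoking = max(find_equilibria(0.05, ModelParams()), key=lambda e: e.C)
Q = ModelParams().f * (smoking.C - 0.05)
print(f"\nsteady-smoker intake at S = 0.05: {Q:.3f} mg/h")
print(
    "Michaelis-Menten check, C(Q) =",
    f"{equilibrium_craving_from_intake(Q, ModelParams()):.4f}",
    "(saturating receptor-activation relation)",
)
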