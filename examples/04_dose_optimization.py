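"""Monte Carlo initial-dose optimization against the 5-10 ng/ml window.

Builds the PTA grid for each comedication x regimen scenario, picks the
argmax dose per weight, and derives weight-banded recommendations on a
fine grid.
"""

from siropk import SimulationScenario, derive_weight_bands, select_optimal_dose, simulate_pta

for oxc in (0, 1):
    for regimen in ("qd", "bid"):
        sc = SimulationScenario(oxc=oxc, regimen=regimen, n_virtual=100_000)
        grid = simulate_pta(sc, seed=0)
        best = select_optimal_dose(grid)
        label = f"{'with' if oxc else 'without'} oxcarbazepine, {regimen}"
        print(f"\n{label}: optimal dose (mg/kg/day) per simulated weight")
        print("  " + "  ".join(f"{w:g}kg:{d:.2f}" for w, d in best.items()))
        rec = derive_weight_bands(scenario=SimulationScenario(
            oxc=oxc, regimen=regimen, n_virtual=50_000), seed=0)
        print("  weight bands: " + "; ".join(
            f"{lo:g}-{hi:g} kg -> {d:.2f}" for lo, hi, d in rec.bands))

# PTA tops out near 35-50% because a 42% clearance CV spreads troughs
# well beyond any fixed window; the argmax dose still identifies the
# best attainable starting point, and it falls with weight (allometry)
# and rises under oxcarbazepine (induced clearance).
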