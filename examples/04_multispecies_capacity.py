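"""How many pathogen species one gel can trap at once.

A gel has a finite pool of matrix binding sites ([M] = 1e5 µm⁻³ for a
2% w/v gel with 10 sites per matrix molecule).  Every anchor species
competes for those sites: slow, high-affinity anchors monopolize them,
fast-exchanging anchors keep them mostly vacant.  Each species is dosed
at the minimum concentration giving a 98% single-species reduction; the
capacity is the species count at which the focal species' D_eff doubles.
"""

from geltrap import competition_parameters, d_eff_exact, from_dimensionless
from geltrap import DimensionlessParameters, species_capacity

results = {}
for tau_ratio in (0.05, 20.0):
    cap = species_capacity(tau_ratio)
    results[tau_ratio] = cap
    print(f"tau_AP/tau_AM = {tau_ratio:>5}: dose = {cap.conc_A_per_species:.2f} anchors/µm³ "
          f"(dimensionless conc {cap.conc_dimless:.2f}), phi* = {cap.phi_star:.2f}, "
          f"capacity = {cap.capacity} species")

ratio = results[20.0].capacity / results[0.05].capacity
print(f"\nfast exchange supports {ratio:.0f}x more species than slow exchange")

cap = results[20.0]
dp = DimensionlessParameters(d_ratio=20.0, N=20, tau_ratio=20.0,
                             conc_dimless=cap.conc_dimless, phi=cap.phi_star)
p = from_dimensionless(dp, R0=10.0 / (21.0 * 4.0), conc_M=1.0e5)
print("\nfocal-species D_eff/D_P vs competing species (fast exchange):")
for m in (1, 1000, 10_000, 50_000, 200_000):
    print(f"  {m:>7} species: {d_eff_exact(competition_parameters(p, m)):.4f}")
print("Trapping is flat until the total anchor load approaches the matrix")
print("site pool, then collapses as sites saturate.")
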