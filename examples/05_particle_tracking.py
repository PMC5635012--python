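"""Synthetic particle-tracking videos analyzed with the MSD pipeline.

Generates 20 s / 66.7 ms / 10 nm-noise switching-diffusion tracks for a
freely diffusing control and for a strongly trapped condition, then runs
the standard multiple-particle-tracking analysis: time-averaged MSD,
per-track D_eff at the 0.2667 s reference lag, the log-log diffusive
exponent, and the mobile fraction (cutoff 10^-1.5 µm²/s).
"""

from geltrap import (
    DimensionlessParameters,
    analyze_tracks,
    d_eff_exact,
    from_dimensionless,
    generate_tracks,
)

conditions = {
    "control (no anchors)": DimensionlessParameters(N=0),
    "anchored gel": DimensionlessParameters(
        d_ratio=20.0, N=15, tau_ratio=5.0, conc_dimless=10.0, phi=0.3),
}

for label, dp in conditions.items():
    p = from_dimensionless(dp, D_P_scale=1.0)  # D_P = 1 µm²/s
    tracks = generate_tracks(p, n_tracks=120, seed=7)
    _, summary = analyze_tracks(tracks)
    model = d_eff_exact(p)
    print(f"{label}:")
    print(f"  model D_eff        = {model:.4f} µm²/s")
    print(f"  tracked <D_eff>    = {summary['mean_d_eff']:.4f} µm²/s "
          f"(geometric {summary['geometric_mean_d_eff']:.4f})")
    print(f"  diffusive exponent = {summary['mean_exponent']:.2f}")
    print(f"  mobile fraction    = {summary['percent_mobile']:.0f}%")

print("\nThe control recovers its input diffusivity with exponent ~1;")
print("the trapped ensemble collapses onto the 10 nm localization-noise")
print("floor: near-zero exponent and a vanishing mobile fraction, the")
print("signature seen when trapping-competent anchors are added to a gel.")
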