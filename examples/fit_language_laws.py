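"""Fit the three statistical laws on synthetic vocabulary data.

Draws a Zipfian occurrence spectrum, grows a two-phase kernel/novelty token
stream, and simulates Menzerath-Altmann-scaled domain lengths, then recovers
the generating parameters with the package's fitters.
"""

from molvocab import (HeapsCurve, SimulationConfig, fit_heaps, fit_ma,
                      fit_zipf, ma_data_from_proteins, occurrence_spectrum,
                      sample_discrete_powerlaw, simulate_kernel_growth,
                      simulate_ma_proteome)
from molvocab.simulate import MAParams

# --- Zipf: occurrence-frequency power law f(k) = C k^-gamma ---------------
draws = sample_discrete_powerlaw(gamma=2.0, xmin=1, n=10_000, seed=7)
zipf = fit_zipf(occurrence_spectrum(draws), xmin=1, bootstrap=100, seed=7)
print(f"Zipf: gamma_hat = {zipf.gamma:.3f} (truth 2.0), "
      f"KS D = {zipf.ks_statistic:.4f}, bootstrap p = {zipf.p_value:.2f}")
print("  -> the tail exponent is recovered from the spectrum alone; the KS "
      "p-value says the draws are consistent with the fitted law.")

# --- Heaps: sublinear vocabulary growth V(N) = K N^beta -------------------
cfg = SimulationConfig(seed=11,
                       innovation_schedule=((0, 2000, 0.9), (2000, 10**9, 0.2)))
_, N, V = simulate_kernel_growth(cfg, n_steps=10_000)
heaps = fit_heaps(HeapsCurve(N=N, V=V), n_segments=2)
for i, seg in enumerate(heaps.segments, 1):
    print(f"Heaps regime {i}: beta = {seg.beta:.2f}, "
          f"N in [{seg.n_range[0]:.0f}, {seg.n_range[1]:.0f}]")
print("  -> the early high-novelty phase grows almost linearly; the late "
      "kernel-reuse phase shows the sublinear slowdown (beta < 1).")

# --- Menzerath-Altmann: z_k = A k^b, "the greater the whole..." -----------
cfg = SimulationConfig(seed=3, ma_params=MAParams(A=200, b=-0.2, sigma=0.05,
                                                  kmax=10, n_per_k=20))
df = simulate_ma_proteome(cfg)
proteins = [(int(g["k"].iloc[0]), g["length"].tolist())
            for _, g in df.groupby("protein_id")]
ma = fit_ma(ma_data_from_proteins(proteins))
print(f"MA: A_hat = {ma.A:.1f} residues (truth 200), "
      f"b_hat = {ma.b:.3f} (truth -0.2), R^2 = {ma.r_squared:.3f}")
print("  -> mean domain length shrinks with domain count: the negative b is "
      "the size-dependent economy signature.")
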