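"""The n-pearl energy landscape: extrema, stability, and critical points.

Evaluates the pearl energy E = sum m_i^(2/3) + chi * sum q_i^2 / m_i^(1/3)
(in units of the single-globule surface energy, charges equilibrated) on the
(n-1)-simplex of mass splits, and prints the stationary-state hierarchy.
"""

from pearlnecklace import (
    chi_critical, find_extremum, stability_transition, symmetric_energy,
)

n = 3
for chi in (0.5, 1.0, 1.5):
    recs = [find_extremum(n, nl, chi) for nl in range(1, n + 1)]
    print(f"chi = {chi}:")
    for rec in recs:
        print(f"  E({rec.nl},{rec.ns}) = {rec.energy:+.4f}  "
              f"masses ({rec.mass_large:.3f}, {rec.mass_small:.3f})  "
              f"{rec.stability} ({rec.n_negative} downhill direction(s))")

# the even split is the HIGHEST saddle below the transition; the single
# large pearl with n-1 equal small pearls is the global minimum.
print(f"\nsymmetric-state energy at chi=1: {symmetric_energy(n, 1.0):+.4f}")
print(f"saddle -> minimum transition of the even split: "
      f"chi* = {stability_transition(n):.4f} (analytically chi = n = {n})")
print(f"fold of the one-large-pearl branch: chi_c = {chi_critical(n, 1):.4f} "
      f"(> n: the asymmetric state survives slightly past the transition)")
print(f"for two pearls the branch merges exactly at the transition: "
      f"chi_c = {chi_critical(2, 1):.4f}")
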