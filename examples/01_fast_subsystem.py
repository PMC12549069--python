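"""The planar fast subsystem: fixed points, stability, and the two local
bifurcation conditions (saddle-node and Hopf).

Prints the equilibria of the cubic-nullcline system at a bistable parameter
point, the discriminant that vanishes on the saddle-node locus, and a Hopf
crossing located on a one-parameter slice.
"""

import numpy as np

from dynamotypes import PlanarParams, fixed_points, hopf_points, sn_residual

# three equilibria: a resting state, a saddle, and a second stable state
p = PlanarParams(mu1=0.0, mu2=1.0, nu=1.0)
print(f"parameters (mu1, mu2, nu) = ({p.mu1}, {p.mu2}, {p.nu})")
for fp in fixed_points(p):
    eig = np.array(fp.eigenvalues)
    print(
        f"  equilibrium x = {fp.location.x:+.3f}: {fp.kind:15s} "
        f"eigenvalues {eig.round(3)}"
    )

# the saddle-node locus is the zero set of the cubic discriminant
print(f"\nSN discriminant at (2, 3): {sn_residual(PlanarParams(2, 3, 0)):.3f} "
      "(zero: a fold of equilibria)")
print(f"SN discriminant at (0, 1): {sn_residual(PlanarParams(0, 1, 0)):.3f} "
      "(positive: three distinct equilibria)")

# a Hopf bifurcation on the slice mu1=0, mu2=-1, nu varying through zero
found = hopf_points(lambda s: PlanarParams(0.0, -1.0, s), np.linspace(-0.5, 0.5, 11))
fp, sign = found[0]
kind = "supercritical" if sign < 0 else "subcritical"
print(f"\nHopf on the nu-slice: x = {fp.location.x:.3f}, {kind} "
      f"(probe sign {sign}) -- a small stable cycle is born as nu falls through 0")
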