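"""Acquire synthetic multi-coil rEPI k-space and reconstruct it jointly.

Distortion arises physically: every readout line is acquired at its own
time, so the off-resonance phase accrued per line shears the image
along the phase-encode axis.  The three echo images are each 3-fold
undersampled (R = 1) and recovered together by structured low-rank
matrix completion; an echo-by-echo SENSE solve serves as the baseline.
"""

from repimap.metrics import nrmse
from repimap.recon import ReconConfig, combine_sos, sense_solve, solve_joint
from repimap.simulate import acquire, make_coils, make_field, make_phantom
from repimap.trajectory import design_repi

n = 66
phantom = make_phantom(n, n, seed=1)
coils = make_coils(n, n, 8, seed=11)
field = make_field(n, n, "mixed", 60.0, seed=21)
traj = design_repi(n, 3, 2, R=1, esp=0.76, te1=31.0)

kspace = acquire(phantom, coils, field, traj, noise_sigma=1 / 40, seed=31)
echoes = solve_joint(kspace, coils, ReconConfig())
magnitude = combine_sos(echoes)

mask = phantom.support_mask
print("echo-by-echo SENSE deviation from the joint reconstruction (NRMSE):")
for e in range(3):
    s = sense_solve(kspace, coils, e)
    print(f"  echo {e}: {nrmse(s, echoes.data[e], mask):.3f}")
print(f"final data-consistency residual: {echoes.meta['residual_trace'][-1]:.4f}")
print("(the SoS-combined magnitude corresponds to the conventional "
      "single-shot EPI image of this protocol)")
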