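"""Detailed vs smoothed biventricular twins under sinus rhythm.

Generates a paired desk-scale anatomy (the detailed twin carries
trabeculae and false tendons; the smoothed twin is the bare shell),
assigns rule-based fibers, runs one sinus beat seeded from the five
initial-activation regions, and prints activation markers plus the
per-lead pseudo-ECG difference between the twins.  Runs in a few minutes.
"""

import numpy as np

from ventric import anatomy, biomarkers as bm, fibers, monodomain as md
from ventric import pseudo_ecg as pe

config = anatomy.BiventricularConfig(trabecular_fraction_target=0.10, seed=1)
detailed, smoothed = anatomy.make_biventricular_pair(config)
frac = anatomy.trabecular_volume_pct(detailed.total_volume(),
                                     smoothed.total_volume())
print(f"trabecular volume: {frac:.1f}% of the detailed myocardium")

spec = md.DiffusionSpec().with_scaled(3.5)  # desk-scale diffusion calibration
ecgs = {}
for name, mesh in (("detailed", detailed), ("smoothed", smoothed)):
    field = fibers.assign_fibers(mesh)
    sites = anatomy.place_iars(mesh)
    result = md.run_simulation(mesh, field, spec, sites, 80.0, sex="male",
                               dt_ms=0.02, init_beats=8)
    tat, tat10, tat90, edi = bm.activation_markers(result, mesh,
                                                   require_complete=False)
    ecgs[name] = pe.compute_pseudo_ecg(result, mesh, field, spec)
    print(f"{name:>9}: TAT {tat:5.1f} ms  TAT10 {tat10:5.1f}  "
          f"TAT90 {tat90:5.1f}  EDI {edi:4.1f} ms")

rmsd = pe.ecg_rmsd(ecgs["detailed"], ecgs["smoothed"])
print("pseudo-ECG RMSD detailed vs smoothed:",
      {k: round(v, 3) for k, v in rmsd.items()}, "(model mV)")
print("\nSub-structures act as activation shortcuts: the twins' activation")
print("maps and QRS complexes differ even though the outer shell is shared.")
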