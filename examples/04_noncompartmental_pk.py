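"""Non-compartmental PK of a simulated 24-min doxorubicin infusion.

Simulates the plasma curve of a 40 mg dose (4 mL x 10 mg/mL) with
biexponential disposition (alpha = 0.13/min, beta = 0.0067/min), sampled
at the 16-point blood-draw schedule, then recovers Cmax/Tmax, the
partitioned trapezoid AUC, apparent clearance and both half-lives —
the elimination half-life should land near ln2/0.0067 = 103 min.
"""

import numpy as np

import geldepot as gd

truth = gd.PKTruth(alpha=0.13, beta=0.0067, dose=40.0, t_admin=24.0,
                   cv_noise=0.05, seed=1)
series = gd.simulate_plasma(truth)
params = gd.nca(series, dose_mg=truth.dose, strip=True)

print(f"Cmax  {params.Cmax:7.0f} ng/mL at Tmax {params.Tmax:.0f} min")
print(f"AUC   administration {params.AUC_admin:6.1f} + post {params.AUC_post:6.1f} "
      f"= total {params.AUC_total:6.1f} ng/mL*h")
print(f"CL/F  {params.CL_F:.4f} mg/(ng/mL)/h")
print(f"t1/2  distribution {params.t_half_alpha:5.1f} min "
      f"(truth {np.log(2) / truth.alpha:.1f}), "
      f"elimination {params.t_half_beta:5.1f} min (truth {np.log(2) / truth.beta:.1f})")
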