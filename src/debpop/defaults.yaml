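# Default parameterization of the size-structured DEB consumer-resource
# model.  Body mass in g, resource density in mg/L, time in days.
Rmax: 30.0     # maximum resource density (mg/L)
delta: 0.01    # resource renewal rate (per day)
Q: 1.0         # maximum ingestion exponent (-)
P: 1.0         # maintenance exponent (-)
M: 0.1         # maximum ingestion constant (g/day)
T: 0.01        # maintenance constant (g/day)
mu_c: 0.0015   # background mortality (per day)
mu_j: 0.0      # additional juvenile mortality (per day)
mu_a: 0.0      # additional adult mortality (per day)
sigma: 0.5     # assimilation efficiency (-)
H: 3.0         # half-saturation density (mg/L)
s_b: 0.1       # body mass at birth (g)
s_j: 1.0       # body mass at maturation (g)
s_m: 10.0      # maximum body mass (g)
s_r: 1.0       # reference body mass (g)
chi: 1.0       # ingestion-to-depletion conversion (mg/L per g)
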