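# Default acquisition-mimicking simulation: four switching diffusion states
# (immobile, slow, medium, fast), the slowest two confined to sub-250-nm
# membrane domains, imaged at 30.5 ms/frame for 300 frames at a particle
# density inside the 0.3-0.6 /um^2 working band.
#
# Diffusion coefficients and switching rates are synthetic choices typical of
# membrane-receptor SMT; they are not measured values.
n_states: 4
D: [0.005, 0.04, 0.15, 0.5]        # um^2/s: immobile, slow, medium, fast
A:
  - [0.92, 0.02666666666666667, 0.02666666666666667, 0.02666666666666667]
  - [0.02666666666666667, 0.92, 0.02666666666666667, 0.02666666666666667]
  - [0.02666666666666667, 0.02666666666666667, 0.92, 0.02666666666666667]
  - [0.02666666666666667, 0.02666666666666667, 0.02666666666666667, 0.92]
pi: [0.25, 0.25, 0.25, 0.25]
confinement: [0.12, 0.22, null, null]   # um; immobile/slow in 90-250 nm domains
sigma_loc: 0.025                   # um per axis
dt: 0.0305                         # s
n_frames: 300
n_tracks: 200                      # per channel
field: 21.0                        # um; 200/21^2 = 0.45 particles/um^2 initially
binding:
  k_on_script: 0.15                # scripted ch2->ch1 binding events per particle per s
  mean_lifetime: 0.3               # s
  bound_offset_sd: 0.03            # um
intensity:
  mu1: 100.0
  cv1: 0.3
  oligomer_weights:                # orders 1..4 per state
    - [0.20, 0.40, 0.25, 0.15]    # immobile: mostly dimers/oligomers
    - [0.50, 0.35, 0.10, 0.05]    # slow
    - [0.65, 0.30, 0.05, 0.00]    # medium
    - [1.00, 0.00, 0.00, 0.00]    # fast: monomeric
bleach_rate: 0.997                 # per-frame survival
seed: 0
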