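# Desk-scale computational box: standard physical parameters, reduced
# domain (fine for colonies up to ~50 um radius / the buckling transition).
nutrient:
  L: 100.0          # half box size (um)
  a: 48.0           # agar depth (um)
  b: 32.0           # headspace above the agar (um)
  grid_mode: uniform
  uniform_spacing: 4.0
numerics:
  dt: 1.0e-4        # inner timestep (h)
  inner_per_outer: 500
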