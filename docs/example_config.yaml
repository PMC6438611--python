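# Example run configuration (all keys optional; defaults shown).
# Units: mm / s / Pa.
scenario:
  name: healthy            # healthy | NSIP | IPF, or a custom name with
  # primary_thickness: 0.025    # explicit parameters (mm)
  # secondary_thickness: 0.025
  # target_resting_volume: 0.512   # mm^3
  material:
    E: 35714.0             # equivalent small-strain modulus, Pa
    nu: 0.42               # Poisson ratio, in [0, 0.5)
waveform:
  p0: 244.0                # pleural amplitude, Pa (~2.5 cmH2O)
  omega: 1.5707963267948966  # pi/2 1/s -> 4 s breathing period
dt: 0.01                   # time step, s
n_cycles: 2                # metrics are computed on the last cycle
fluid_mode: network        # duct-network Stokes (cycle default)
solid_mode: shell          # Neo-Hookean septal shell
mesh_level: 1              # shell subdivision level (0 = coarsest)
tolerance: 1.0e-6          # FSI sub-iteration displacement residual
newton_rtol: 1.0e-8        # solid Newton relative residual
loose_coupling: false      # true = single exchange per step
seed: 0
output_dir: results
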