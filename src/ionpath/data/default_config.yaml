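# Default pipeline configuration.
#
# Lines marked "# assumed" carry values chosen by this package for the
# desk-scale toy system; the remaining numerical settings echo the
# published simulation protocol for this class of calculation.

system:
  n_sites: 8
  site_spacing: 3.1        # assumed (typical K+ filter carbonyl-cage spacing)
  well_depths: 3.0         # assumed, kcal/mol
  barrier_heights: 2.5     # assumed, kcal/mol
  repulsion_strength: 20.0 # assumed, kcal*A/mol
  screening_length: 2.0    # assumed, A
  n_ions: 3
  temperature: 310.0       # K

path:
  n_frames: 16
  lambda: null             # A^-2; null -> set so lambda * <adjacent MSD> = 9.21

metadynamics:
  height: 0.06             # kcal/mol per hill
  deposition_period: 2.0   # ps (one hill per 2 ps = 0.5 ps^-1)
  widths: [0.2, 0.2, 0.1]  # sigma for s, z, n_theta
  wall_z_max: 3.5          # A^2 upper wall on the path distance Z
  wall_ntheta_min: 5.0     # lower wall on N_S2,S3
  wall_k: 10.0             # assumed, kcal/mol per unit^2
  n_walkers: 1             # assumed for the desk-scale demo (up to 10 supported)
  n_steps: 400000          # assumed, Langevin steps of the demo run
  dt: 0.005                # assumed, ps
  diffusion: 0.5           # assumed, A^2/ps
  stride: 40               # assumed, recording stride
  oned_rate: 0.02          # kcal/mol/ps Gaussian deposition rate, 1D runs
  oned_width: 0.1          # CV units, 1D runs

fes:
  n_bins: 60               # assumed
  average_last_fraction: 0.25  # assumed
  min_basin_depth: 0.5     # assumed, kcal/mol

reweight:
  burn_in: 0.5             # assumed
  n_bins: 60               # assumed

kmc:
  voltage: -40.0           # mV
  conc_in: 100.0           # mM
  conc_out: 100.0          # mM
  total_time: 5.0          # microseconds
  entry_rate_scale: 0.05   # assumed, 1/(ns mM)
  diffusion: 0.5           # assumed, A^2/ns

iv:
  voltages: [-80.0, -40.0, 40.0, 80.0]   # assumed, mV

seed: 2012
outdir: ionpath_out
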