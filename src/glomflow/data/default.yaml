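# Default run configuration.  Every value here is echoed verbatim into the
# run log of each study, so a run is reproducible from its log alone.

physio:
  p_bs: 14.0                   # Bowman's-space pressure, mmHg
  p_downstream: 15.0           # pressure downstream of the efferent resistor, mmHg
  systemic_hematocrit: 0.5     # afferent hematocrit (convention, not measured)
  afferent_protein_conc: 5.7   # afferent plasma protein, g/dL (convention)
  wall_thickness_default: 0.2  # capillary wall thickness, µm (assumed)

rheology:
  oncotic: [2.1, 0.16, 0.009]  # Landis–Pappenheimer cubic, mmHg per (g/dL)^n
  plasma_visc_base: 0.9        # plasma viscosity at C=0, cP
  plasma_visc_slope: 0.0614    # cP per g/dL  (≈1.25 cP at 5.7 g/dL)
  ps_a: -6.96                  # phase separation: diameter-asymmetry coefficient
  ps_b: 6.98                   # phase separation: slope coefficient
  ps_x0: 0.4                   # phase separation: plasma-skimming threshold, µm

solver:
  tol: 1.0e-06                  # max relative change of R_f and µ at convergence
  max_iter: 400
  relaxation: 0.5              # under-relaxation engaged on oscillation
  r_f_max: 1.0e+09               # clamp marking a segment non-filtering, mmHg·min/nL
  pgc_mode: length             # P_GC averaging: length | segment | flow
  afferent_diameter: 20.0      # feeding-vessel diameter at the entry node, µm
  max_hematocrit: 0.95

generator:
  seed: 1
  n_lobules: 3
  n_segments: 320
  n_nodes: 193
  diameter_median: 7.0         # µm, lognormal median
  diameter_sigma: 0.25
  length_median: 50.0          # µm, lognormal median
  length_sigma: 0.4
  wall_thickness: 0.2          # µm
  lobule_bias: 0.0
  max_width: 8

network_file: null             # path to an edge-list CSV/JSON; null -> generator
conditions_file: null          # conditions CSV; null -> packaged four-condition study
output_dir: glomflow_out
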