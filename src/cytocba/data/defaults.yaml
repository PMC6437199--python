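# Default pipeline configuration.  Protocol constants are named here,
# never inlined: the 0.5% PE background rate, the 1.0 index cutoff and
# the 50-year onset-age boundary.
gating:
  central_mass: 0.90        # live-gate ellipsoid mass
  fsc_floor: 15000.0        # debris floor on forward scatter
  aad_threshold: 1000.0     # 7-AAD dead-cell boundary (arbitrary units)
  gfp_mode: different       # per-cell-line GFP cut-off lines
  gfp_tail_rate: 0.001      # parental GFP cut-off = 99.9th percentile
  min_population: 100
  min_events: 50
  robust_iterations: 3
index:
  background_rate: 0.5      # percent of control events above PE threshold
  cutoff: 1.0               # seropositive iff index strictly > cutoff
  denominator_floor: 0.5    # percent; floors the parental PE fraction
cohort:
  age_cutoff: 50.0          # years; onset age at/above this is late-onset
  sd_ddof: 1
simulation:
  n_events: 10000           # desk-scale stand-in for 5.0e6 assay cells
  events_per_million: 2000
  debris_fraction: 0.10
  dead_fraction: 0.05
  transfection_efficiency: 0.60
  dilution: 100             # reciprocal serum dilution (assay protocol 1:100)
  secondary_dilution: 1000  # PE-labelled secondary antibody at 1:1000
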