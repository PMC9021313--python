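# Default global groundwater DOC flux scenario.
# Literature inputs (not measured by this package):
#   volumes  : annual groundwater volume fluxes, km3 yr-1
#   concentrations : global groundwater DOC concentration estimates, mg C L-1
volumes:
  sgd: 2400.0          # subterranean groundwater discharge to coastal oceans
  extraction: 982.0    # global groundwater extraction (irrigation/domestic/industrial)
concentrations:
  median: 1.2
  mean: 3.8
projection:
  extraction_2099: 1621.0   # projected annual global extraction, km3 yr-1
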