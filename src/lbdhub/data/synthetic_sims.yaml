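# Study plan for the synthetic planted-truth benchmark graphs: two
# depth-2 target simulations plus their intersection, from which hub
# nodes are selected for hub network analysis.
defaults:
  allowed_semtypes: [AAPP, GNGM, HORM]
  depth: 2
  damping: 0.4
  combine: mean
simulations:
  A6:
    description: Source nodes related to disease alpha
    targets: [C9000001]
  A5:
    description: Source nodes related to disease beta
    targets: [C9000002]
  A4:
    description: Intersection of A5 and A6, filtered to select hub nodes
    intersect_of: [A5, A6]
hub_order: [A1, A2, A3]
k: 10
min_frequency: 2
hub_criteria:
  min_percentile: 50.0
  min_metapath_count: 10
  n_hubs: 3
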