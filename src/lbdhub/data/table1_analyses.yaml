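# Six-analysis study plan linking COVID-19 and resistant hypertension
# through three renin–angiotensin–aldosterone system (RAAS) hub nodes.
# Target concepts are real UMLS CUIs; source nodes are constrained to
# proteins (AAPP), genes (GNGM) and hormones (HORM) at search depth 2.
defaults:
  allowed_semtypes: [AAPP, GNGM, HORM]
  depth: 2
  damping: 0.4
  combine: mean
simulations:
  A6:
    description: Source nodes related to COVID-19
    targets: [C5203670]
  A5:
    description: Source nodes related to resistant hypertension
    targets: [C0745130]
  A4:
    description: >-
      Intersection of high-ranking A5 and A6 source nodes, filtered to
      select hub nodes for the cross-domain analyses A1-A3
    intersect_of: [A5, A6]
  A1:
    description: Mineralocorticoid receptor (RAAS hub) with COVID-19
    targets: [C0066563, C5203670]
  A2:
    description: Epithelial sodium channel (RAAS hub) with COVID-19
    targets: [C0384156, C5203670]
  A3:
    description: AT1 receptor (RAAS hub) with COVID-19
    targets: [C0529330, C5203670]
hub_order: [A1, A2, A3]
k: 10
min_frequency: 2
hub_criteria:
  min_percentile: 50.0
  min_metapath_count: 10
  n_hubs: 3
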