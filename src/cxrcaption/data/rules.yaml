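# Rule-based caption generation: the 23 signs partitioned into 8 expression
# subcategories, each with a positive sentence pattern ({sign} slot) and a
# negative sentence emitted when every member is negative. Subcategory 1
# (focal lung densities, incl. pneumothorax) and its two sentences follow
# the published wording; the remaining groupings and sentences are this
# package's editable stand-in.
subcategories:
  - id: 1
    members: [consolidation, small consolidation, patchy consolidation, nodule,
              calcification, mass, emphysema, pulmonary edema, cavity, pneumothorax]
    positive_template: "{sign} is observed in the lung."
    negative_text: "there are no abnormal densities in both lung fields."
    emit_negative_when_all_negative: true
  - id: 2
    members: [interstitial disease, thickened bronchovascular markings]
    positive_template: "{sign} is observed in both lungs."
    negative_text: "the lung markings are clear and regular."
    emit_negative_when_all_negative: true
  - id: 3
    members: [hilar adenopathy]
    positive_template: "{sign} is observed at the hilum."
    negative_text: "both hila are normal in size and density."
    emit_negative_when_all_negative: true
  - id: 4
    members: [cardiomegaly]
    positive_template: "{sign} is observed on the frontal view."
    negative_text: "the heart shadow is normal in size and shape."
    emit_negative_when_all_negative: true
  - id: 5
    members: [aortic unfolding, aortic arteriosclerosis]
    positive_template: "{sign} is observed in the mediastinum."
    negative_text: "the aortic silhouette is unremarkable."
    emit_negative_when_all_negative: true
  - id: 6
    members: [pleural effusion, pleural thickening, pleural adhesion, pleural calcification]
    positive_template: "{sign} is observed."
    negative_text: "no pleural effusion or pleural thickening is seen."
    emit_negative_when_all_negative: true
  - id: 7
    members: [scoliosis]
    positive_template: "{sign} is observed in the thoracic spine."
    negative_text: "the thoracic cage is symmetric and intact."
    emit_negative_when_all_negative: true
  - id: 8
    members: [peripherally inserted central catheter implant, pacemaker implant]
    positive_template: "{sign} is observed."
    negative_text: ""
    emit_negative_when_all_negative: false
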