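# The 23-sign abnormal-finding vocabulary for frontal chest radiographs.
# Order is load-bearing: sign_id = list position and defines the bit order
# of every label code. Grouping runs lung parenchyma -> mediastinum ->
# pleura -> thorax. Lexicons hold surface phrases (synonyms/parasynonyms)
# that may appear in report text; the canonical name is always included.
signs:
  - name: consolidation
    group: lung_parenchyma
    lexicon: [consolidation, airspace opacity, dense opacity]
  - name: small consolidation
    group: lung_parenchyma
    lexicon: [small consolidation, small airspace opacity]
  - name: patchy consolidation
    group: lung_parenchyma
    lexicon: [patchy consolidation, patchy opacity, patchy shadowing]
  - name: nodule
    group: lung_parenchyma
    lexicon: [nodule, nodular opacity, nodular shadow]
  - name: calcification
    group: lung_parenchyma
    lexicon: [calcification, calcified focus, calcified density]
  - name: mass
    group: lung_parenchyma
    lexicon: [mass, mass lesion]
  - name: interstitial disease
    group: lung_parenchyma
    lexicon: [interstitial disease, interstitial change, reticular pattern]
  - name: cavity
    group: lung_parenchyma
    lexicon: [cavity, cavitary lesion, cavitation]
  - name: hilar adenopathy
    group: lung_parenchyma
    lexicon: [hilar adenopathy, hilar lymphadenopathy, enlarged hilum]
  - name: emphysema
    group: lung_parenchyma
    lexicon: [emphysema, emphysematous change, hyperinflation]
  - name: pulmonary edema
    group: lung_parenchyma
    lexicon: [pulmonary edema, pulmonary oedema, alveolar edema]
  - name: thickened bronchovascular markings
    group: lung_parenchyma
    lexicon: [thickened bronchovascular markings, increased bronchovascular markings,
              accentuated lung markings]
  - name: cardiomegaly
    group: mediastinum
    lexicon: [cardiomegaly, enlarged cardiac silhouette, enlarged heart shadow]
  - name: aortic unfolding
    group: mediastinum
    lexicon: [aortic unfolding, unfolded aorta, elongated aorta]
  - name: aortic arteriosclerosis
    group: mediastinum
    lexicon: [aortic arteriosclerosis, aortic atherosclerosis, calcified aortic knob]
  - name: pneumothorax
    group: pleura
    lexicon: [pneumothorax, pleural air]
  - name: pleural effusion
    group: pleura
    lexicon: [pleural effusion, pleural fluid, costophrenic angle blunting]
  - name: pleural thickening
    group: pleura
    lexicon: [pleural thickening, thickened pleura]
  - name: pleural adhesion
    group: pleura
    lexicon: [pleural adhesion, pleural adhesions]
  - name: pleural calcification
    group: pleura
    lexicon: [pleural calcification, calcified pleura, calcified pleural plaque]
  - name: scoliosis
    group: thorax
    lexicon: [scoliosis, spinal curvature, curved spine]
  - name: peripherally inserted central catheter implant
    group: thorax
    lexicon: [peripherally inserted central catheter implant, picc line, picc catheter]
  - name: pacemaker implant
    group: thorax
    lexicon: [pacemaker implant, pacemaker, cardiac pacing device]
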