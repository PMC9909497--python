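# Location phrases blanked out of token sequences before medoid selection
# and caption output (one phrase per line; matched longest-first on tokens).
right upper lobe
right middle lobe
right lower lobe
left upper lobe
left lower lobe
right upper zone
right mid zone
right lower zone
left upper zone
left mid zone
left lower zone
right hemithorax
left hemithorax
right costophrenic angle
left costophrenic angle
right apex
left apex
right base
left base
bilateral
retrocardiac
perihilar
subpleural
right
left
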