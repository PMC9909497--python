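the lungs are well inflated and clear. the cardiac silhouette and mediastinal contours are within normal limits. both costophrenic angles are sharp. the visualized bony thorax is intact. no acute cardiopulmonary abnormality is identified.
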