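# Synthetic sentence banks emulating highly standardised chest-X-ray reports:
# one sentence per anatomical topic, heavily shared normal phrasing, negation
# cues in normal sentences, positive finding mentions in abnormal ones.
# Authored for this package; real reports are only emulated qualitatively.
topics:
  - name: heart
    category: cardiomegaly
    normal:
      - "the heart is normal in size and contour"
      - "the cardiac silhouette and mediastinum are within normal limits"
      - "heart size is within normal limits for technique"
    abnormal:
      - "there is stable moderate cardiomegaly without pericardial effusion"
      - "the heart is enlarged with moderate cardiomegaly noted"
      - "marked cardiomegaly with a tortuous thoracic aorta is seen"
  - name: lungs
    category: pleural_effusion
    normal:
      - "the lungs are clear without focal airspace disease"
      - "no pneumothorax or pleural effusion is identified"
      - "the lungs are clear and expanded bilaterally"
    abnormal:
      - "there is a small right sided pleural effusion"
      - "bilateral layering pleural effusions are again demonstrated"
      - "a moderate left pleural effusion has increased in size"
  - name: vasculature
    category: edema
    normal:
      - "there is no evidence of pulmonary edema"
      - "the pulmonary vascularity is normal in appearance"
      - "no pulmonary vascular congestion is seen"
    abnormal:
      - "mild interstitial pulmonary edema is present"
      - "there is worsening pulmonary vascular congestion"
      - "moderate pulmonary edema with perihilar haziness is seen"
  - name: bones
    category: fracture
    normal:
      - "the visualized bony structures are intact"
      - "no acute bony abnormality is identified"
      - "the thoracic spine is unchanged without acute findings"
    abnormal:
      - "an acute fracture of the right rib is noted"
      - "there are old healed rib fractures on the left"
      - "acute fracture of the left clavicle is seen"
template_weights: [0.6, 0.25, 0.15]
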