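# Synthetic toy finding lexicon (authored for this package; not the external
# rule engine).  A category is positive when a mention phrase occurs with no
# negation cue in the `window` tokens immediately preceding the match.
window: 3
cues: ["no", "without", "negative"]
categories:
  enlarged_cardiomediastinum:
    phrases:
      - [mediastinal, widening]
      - [widened, mediastinum]
  cardiomegaly:
    phrases:
      - [cardiomegaly]
      - [enlarged, heart]
  lung_opacity:
    phrases:
      - [opacity]
      - [opacities]
  lung_lesion:
    phrases:
      - [nodule]
      - [pulmonary, mass]
  edema:
    phrases:
      - [pulmonary, edema]
      - [vascular, congestion]
  consolidation:
    phrases:
      - [consolidation]
  pneumonia:
    phrases:
      - [pneumonia]
      - [infectious, process]
  atelectasis:
    phrases:
      - [atelectasis]
  pneumothorax:
    phrases:
      - [pneumothorax]
  pleural_effusion:
    phrases:
      - [pleural, effusion]
      - [pleural, effusions]
  pleural_other:
    phrases:
      - [pleural, thickening]
  fracture:
    phrases:
      - [fracture]
      - [fractures]
  support_devices:
    phrases:
      - [endotracheal, tube]
      - [central, catheter]
      - [pacemaker]
  no_finding:
    phrases:
      - [completely, unremarkable, study]
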