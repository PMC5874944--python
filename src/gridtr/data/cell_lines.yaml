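# Radiosensitivity catalogue.
#
# "classes" are the three reference tumour groups defined by SF2 relative
# to the 0.4 threshold; all tumours use alpha/beta = 10 Gy.  "normal" is
# the conventional normal-tissue reference (SF2 = 0.4, alpha/beta = 2.5 Gy).
# "histologies" carry published SF2 values by tumour type.
classes:
  radiosensitive:
    sf2: 0.2
    alpha_beta: 10.0
  semisensitive:
    sf2: 0.4
    alpha_beta: 10.0
  radioresistant:
    sf2: 0.5
    alpha_beta: 10.0
normal:
  sf2: 0.4
  alpha_beta: 2.5
histologies:
  larynx: {sf2: 0.45, alpha_beta: 10.0}
  base_of_tongue: {sf2: 0.40, alpha_beta: 10.0}
  nasopharynx: {sf2: 0.45, alpha_beta: 10.0}
  retromolar_trigone: {sf2: 0.64, alpha_beta: 10.0}
  parotid: {sf2: 0.28, alpha_beta: 10.0}
  sarcoma: {sf2: 0.42, alpha_beta: 10.0}
  melanoma: {sf2: 0.48, alpha_beta: 10.0}
  scc: {sf2: 0.48, alpha_beta: 10.0}
  adenocarcinoma: {sf2: 0.40, alpha_beta: 10.0}
  osteosarcoma: {sf2: 0.42, alpha_beta: 10.0}
  liposarcoma: {sf2: 0.24, alpha_beta: 10.0}
  leiomyosarcoma: {sf2: 0.55, alpha_beta: 10.0}
  colorectal: {sf2: 0.40, alpha_beta: 10.0}
  tonsil: {sf2: 0.38, alpha_beta: 10.0}
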