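histology	sf2
Larynx	0.45
Base of tongue	0.40
Nasopharynx	0.45
Retromolar trigone	0.64
Parotid	0.28
Sarcoma	0.42
Melanoma	0.48
SCC	0.48
Adenocarcinoma	0.40
Osteosarcoma	0.42
Liposarcoma	0.24
Leiomyosarcoma	0.55
Colorectal	0.40
Tonsil	0.38
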