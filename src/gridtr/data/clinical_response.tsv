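study	histology	response_percent	qualifier	delivery
mohiuddin_a	Osteosarcoma	100	=	block
mohiuddin_a	Liposarcoma	50	=	block
mohiuddin_a	Leiomyosarcoma	100	=	block
mohiuddin_a	Colorectal	100	=	block
mohiuddin_b	Sarcoma	94	=	block
mohiuddin_b	SCC	92	=	block
mohiuddin_b	Melanoma	83	=	block
mohiuddin_b	Adenocarcinoma	69	=	block
mohiuddin_c	Sarcoma	83	=	block
mohiuddin_c	SCC	94	=	block
mohiuddin_c	Adenocarcinoma	94	=	block
mohiuddin_c	Melanoma	50	=	block
sathishkumar	SCC	100	=	block
sathishkumar	Adenocarcinoma	90	>=	block
sathishkumar	Melanoma	80	>=	block
huhn	SCC of H&N	93	=	block
penagaricano	Parotid		=	MLC
penagaricano	Base of tongue	30	=	MLC
penagaricano	Maxillary sinus	50	=	MLC
penagaricano	Nasopharynx	100	=	MLC
penagaricano	Retromolar trigone	100	=	MLC
penagaricano	Larynx	100	=	MLC
penagaricano	Tonsil	25	=	MLC
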