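set_id	set_name	ko
ko02020	Two-component system	K07642
ko02020	Two-component system	K18889
ko02020	Two-component system	K18148
ko02020	Two-component system	K07778
ko02020	Two-component system	K07637
ko02020	Two-component system	K02476
ko00052	Galactose metabolism	K10111
ko00052	Galactose metabolism	K12112
ko00052	Galactose metabolism	K01894
ko00052	Galactose metabolism	K00849
ko00052	Galactose metabolism	K01784
ko00910	Nitrogen metabolism	K00362
ko00910	Nitrogen metabolism	K00363
ko00910	Nitrogen metabolism	K02567
ko00910	Nitrogen metabolism	K02568
ko00910	Nitrogen metabolism	K00368
ko02026	Biofilm formation	K11935
ko02026	Biofilm formation	K11936
ko02026	Biofilm formation	K11937
ko02026	Biofilm formation	K12687
ko00010	Glycolysis / Gluconeogenesis	K00844
ko00010	Glycolysis / Gluconeogenesis	K01810
ko00010	Glycolysis / Gluconeogenesis	K00850
ko00010	Glycolysis / Gluconeogenesis	K01623
ko00010	Glycolysis / Gluconeogenesis	K00134
ko02010	ABC transporters	K10240
ko02010	ABC transporters	K17329
ko02010	ABC transporters	K17330
ko02010	ABC transporters	K10112
ko00620	Pyruvate metabolism	K00027
ko00620	Pyruvate metabolism	K00161
ko00620	Pyruvate metabolism	K00162
ko00620	Pyruvate metabolism	K01512
ko00230	Purine metabolism	K00088
ko00230	Purine metabolism	K01756
ko00230	Purine metabolism	K00602
ko00230	Purine metabolism	K01923
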