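# Steroidogenesis pathway edge list: substrate <TAB> product <TAB> enzyme.
# One directed edge per line; lines starting with '#' are comments.
# Users may amend this file and load it with steroidratio.pathway.load_pathway.
cholesterol	pregnenolone	P450scc
pregnenolone	progesterone	3b-HSD
pregnenolone	17-OH-pregnenolone	P450C17
17-OH-pregnenolone	DHEA	P450C17
17-OH-pregnenolone	17-OH-progesterone	3b-HSD
progesterone	17-OH-progesterone	P450C17
progesterone	11-deoxycorticosterone	21-hydroxylase
17-OH-progesterone	11-deoxycortisol	21-hydroxylase
17-OH-progesterone	androstenedione	P450C17
DHEA	DHEAS	sulfotransferase
DHEA	androstenedione	3b-HSD
11-deoxycorticosterone	corticosterone	11b-hydroxylase
11-deoxycortisol	cortisol	11b-hydroxylase
corticosterone	aldosterone	aldosterone-synthase
androstenedione	testosterone	17b-HSD
testosterone	DHT	5a-reductase
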