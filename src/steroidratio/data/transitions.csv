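analyte,transition,parent_mz,fragment_mz,rt_min
aldosterone,1,359.2,189.1,5.56
aldosterone,2,359.2,331.3,5.56
corticosterone,1,347.1,121.1,
corticosterone,2,347.1,97.1,
cortisol,1,363.1,115.1,5.56
cortisol,2,363.1,121,5.56
11-deoxycortisol,1,347.11,97,
11-deoxycortisol,2,347.11,109,
androstenedione,1,287.1,97,
androstenedione,2,287.1,109,
testosterone,1,289.1,97,
testosterone,2,289.1,109,
DHEA,1,271.2,213.1,9.30
DHEA,2,271.2,253.2,9.30
DHEAS,1,271.2,197.1,6.89
DHEAS,2,271.2,213.2,6.89
17-OH-progesterone,1,331,97,
17-OH-progesterone,2,331,109,
progesterone,1,315.1,97,
progesterone,2,315.1,109,
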