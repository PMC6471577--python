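gene	event_type	delta_psi	p_value	event_id
TFPI	AF	0.35943	0	2:187503770-187513616:187513641:187503770-187554200:187554492:-
TFPI	AF	0.33763	1.349e-2	2:187503770-187513616:187513653:187503770-187554200:187554492:-
TFPI	AF	-0.23995	3.853e-2	2:187503770-187513616:187519860:187503770-187554200:187554438:-
WARS	AF	0.69358	4.496e-2	14:100369258-100375283:100375473:100369258-100376260:100376308:-
PSG6	AF	-0.20069	2.922e-2	19:42910858-42916125:42916398:42910858-42917729:42917887:-
C1QTNF1	AF	-0.31195	3.996e-2	17:79022934:79023088-79043955:79025663:79025935-79043955:+
C1QTNF1	AF	-0.21092	4.396e-2	17:79024070:79024494-79043955:79025663:79025935-79043955:+
C1QTNF1	AF	-0.33645	4.396e-2	17:79024261:79024494-79046555:79043593:79044123-79046555:+
S100A13	AF	-0.22921	4.795e-2	1:153626533-153626951:153627048:153626533-153628121:153628180:-
S100A13	AF	-0.20534	4.795e-2	1:153626533-153627139:153627268:153626533-153628121:153628180:-
PSG6	AL	-0.20069	2.922e-2	19:42906636:42907176-42910580:42907725:42907854-42910580:-
TFPI	MX	-0.21823	3.853e-2	2:187503770-187513616:187513646-187554200:187503770-187520542:187520613-187554200:-
TFPI	SE	0.12683	3.853e-2	2:187503770-187529364:187529485-187554200:-
EVI5	SE	-0.30817	4.795e-2	1:92636336-92663420:92663452-92665939:-
PSME2	SE	-0.28553	4.895e-2	14:24145772-24146208:24146240-24146534:-
ADGRG6	SE	-0.28155	3.497e-2	6:142438364-142440908:142440953-142443337:+
SIN3B	SE	0.09338	4.595e-2	19:16862559-16862884:16862979-16863680:+
SCEL	SE	0.35527	4.412e-2	13:77591460-77593514:77593573-77597545:+
C1QTNF1	SE	0.23831	4.396e-2	17:79024494-79043955:79044123-79046555:+
PSAP	SE	-0.09818	2.597e-2	10:71822007-71823888:71823896-71825837:-
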