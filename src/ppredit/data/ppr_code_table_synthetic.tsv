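# Synthetic reconstruction of published PPR-code combination preferences.
# Configuration, not measured data: substitute a curated weighting table
# for production target prediction.
class	aa6	aa1prime	pA	pC	pG	pU
P	A	D	0.1200	0.2500	0.1300	0.5000
P	G	D	0.1000	0.2000	0.1000	0.6000
P	G	N	0.1500	0.3000	0.1500	0.4000
P	G	S	0.1200	0.3000	0.1300	0.4500
P	I	D	0.1700	0.2500	0.1800	0.4000
P	I	N	0.3500	0.2200	0.1800	0.2500
P	N	D	0.0500	0.1500	0.0800	0.7200
P	N	E	0.1200	0.3000	0.1300	0.4500
P	N	G	0.1200	0.4500	0.1300	0.3000
P	N	N	0.0800	0.4700	0.0700	0.3800
P	N	S	0.1000	0.5800	0.0800	0.2400
P	N	T	0.1200	0.4000	0.1300	0.3500
P	S	C	0.4500	0.2000	0.1500	0.2000
P	S	D	0.1500	0.1000	0.5500	0.2000
P	S	G	0.5000	0.1500	0.2000	0.1500
P	S	N	0.6500	0.1000	0.1000	0.1500
P	S	S	0.1500	0.4500	0.1000	0.3000
P	S	T	0.4000	0.2000	0.2000	0.2000
P	T	D	0.1000	0.0400	0.7800	0.0800
P	T	E	0.2500	0.1200	0.4500	0.1800
P	T	G	0.5000	0.1000	0.2800	0.1200
P	T	N	0.7100	0.0500	0.1600	0.0800
P	T	S	0.5500	0.1000	0.2500	0.1000
P	T	T	0.3500	0.1500	0.3000	0.2000
P	V	T	0.1800	0.3500	0.1700	0.3000
L	A	D	0.1850	0.2500	0.1900	0.3750
L	G	D	0.1750	0.2250	0.1750	0.4250
L	G	N	0.2000	0.2750	0.2000	0.3250
L	G	S	0.1850	0.2750	0.1900	0.3500
L	I	D	0.2100	0.2500	0.2150	0.3250
L	I	N	0.3000	0.2350	0.2150	0.2500
L	N	D	0.1500	0.2000	0.1650	0.4850
L	N	E	0.1850	0.2750	0.1900	0.3500
L	N	G	0.1850	0.3500	0.1900	0.2750
L	N	N	0.1650	0.3600	0.1600	0.3150
L	N	S	0.1750	0.4150	0.1650	0.2450
L	N	T	0.1850	0.3250	0.1900	0.3000
L	S	C	0.3500	0.2250	0.2000	0.2250
L	S	D	0.2000	0.1750	0.4000	0.2250
L	S	G	0.3750	0.2000	0.2250	0.2000
L	S	N	0.4500	0.1750	0.1750	0.2000
L	S	S	0.2000	0.3500	0.1750	0.2750
L	S	T	0.3250	0.2250	0.2250	0.2250
L	T	D	0.1750	0.1450	0.5150	0.1650
L	T	E	0.2500	0.1850	0.3500	0.2150
L	T	G	0.3750	0.1750	0.2650	0.1850
L	T	N	0.4800	0.1500	0.2050	0.1650
L	T	S	0.4000	0.1750	0.2500	0.1750
L	T	T	0.3000	0.2000	0.2750	0.2250
L	V	T	0.2150	0.3000	0.2100	0.2750
S	A	D	0.1200	0.2500	0.1300	0.5000
S	G	D	0.1000	0.2000	0.1000	0.6000
S	G	N	0.1500	0.3000	0.1500	0.4000
S	G	S	0.1200	0.3000	0.1300	0.4500
S	I	D	0.1700	0.2500	0.1800	0.4000
S	I	N	0.3500	0.2200	0.1800	0.2500
S	N	D	0.0500	0.1500	0.0800	0.7200
S	N	E	0.1200	0.3000	0.1300	0.4500
S	N	G	0.1200	0.4500	0.1300	0.3000
S	N	N	0.0800	0.4700	0.0700	0.3800
S	N	S	0.1000	0.5800	0.0800	0.2400
S	N	T	0.1200	0.4000	0.1300	0.3500
S	S	C	0.4500	0.2000	0.1500	0.2000
S	S	D	0.1500	0.1000	0.5500	0.2000
S	S	G	0.5000	0.1500	0.2000	0.1500
S	S	N	0.6500	0.1000	0.1000	0.1500
S	S	S	0.1500	0.4500	0.1000	0.3000
S	S	T	0.4000	0.2000	0.2000	0.2000
S	T	D	0.1000	0.0400	0.7800	0.0800
S	T	E	0.2500	0.1200	0.4500	0.1800
S	T	G	0.5000	0.1000	0.2800	0.1200
S	T	N	0.7100	0.0500	0.1600	0.0800
S	T	S	0.5500	0.1000	0.2500	0.1000
S	T	T	0.3500	0.1500	0.3000	0.2000
S	V	T	0.1800	0.3500	0.1700	0.3000
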