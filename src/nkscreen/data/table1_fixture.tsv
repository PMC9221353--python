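# Dual-day screen hits: compounds with co-culture fold-change >= 1.3 over
# DMSO on both screening days of the 1200-compound approved-drug screen.
# fold_change is the reported aggregate over the two replicate days
# (single_replicate marks the one compound reported from a single day);
# candidate marks the compounds selected for dose-response follow-up.
rank	compound_id	name	fold_change	drug_class	candidate	single_replicate
1	colistin_sulfate_salt	Colistin sulfate salt	2.02	antibiotic	true	true
2	nicotinamide	Nicotinamide	1.85	vitamin B3	true	false
3	monensin_sodium_salt	Monensin sodium salt	1.62	antibiotic	true	false
4	butirosin_disulfate_salt	Butirosin disulfate salt	1.60	aminoglycoside antibiotic	false	false
5	zafirlukast	Zafirlukast	1.54	anti-asthmatic	true	false
6	amphotericin_b	Amphotericin B	1.50	antifungal	false	false
7	argatroban	Argatroban	1.46	anti-coagulant	false	false
8	dimethisoquin_hydrochloride	Dimethisoquin hydrochloride	1.45	anesthetic	false	false
9	tizanidine_hydrochloride	Tizanidine hydrochloride	1.42	adrenergic agonist	true	false
10	closantel	Closantel	1.41	anti-parasitic	true	false
11	benazepril_hydrochloride	Benazepril hydrochloride	1.40	ACE inhibitor	true	false
12	diflorasone_diacetate	Diflorasone diacetate	1.40	topical steroid	true	false
13	butoconazole_nitrate	Butoconazole nitrate	1.38	anti-fungal	false	false
14	etretinate	Etretinate	1.34	retinoid	false	false
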