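segment_id	segment_type	chain	cys_anchor	fw_anchor	functional	source_accession
TRGV1	V	TRG	132		false	
TRGV2	V	TRG	132		true	
TRGV3	V	TRG	132		true	
TRGV4	V	TRG	132		true	
TRGV5	V	TRG	132		true	
TRGV5P	V	TRG	132		false	
TRGV6	V	TRG	132		false	
TRGV7	V	TRG	132		false	
TRGV8	V	TRG	132		true	
TRGV10	V	TRG	132		false	
TRGV11	V	TRG	132		false	
TRGVA	V	TRG	132		false	
TRGVB	V	TRG	132		false	
TRGV9	V	TRG	132		true	
TRGJP	J	TRG		27	true	
TRGJ2	J	TRG		18	true	
TRGJ1	J	TRG		18	true	
TRGJP1	J	TRG		24	true	
TRGJP2	J	TRG		24	true	
TRGC1	C	TRG			true	M14996;M14997;M14998
TRGC2	C	TRG			true	M14002
TRDV1	V	TRD	132		true	
TRDV2	V	TRD	132		true	
TRDV3	V	TRD	132		true	
TRDV4/TRAV14	V	TRD	132		true	
TRDV5/TRAV29	V	TRD	132		true	
TRDV6/TRAV23	V	TRD	132		true	
TRDV7/TRAV36	V	TRD	132		true	
TRDV8/TRAV38-2	V	TRD	132		true	
TRDD1	D	TRD			true	
TRDD2	D	TRD			true	
TRDD3	D	TRD			true	
TRDJ1	J	TRD		21	true	
TRDJ2	J	TRD		21	true	
TRDJ3	J	TRD		21	true	
TRDJ4	J	TRD		18	true	
TRDC	C	TRD			true	M22149;M22150;M22151
TRAC	C	TRA			true	X02883
TRBC1	C	TRB			true	M12887;L36092
TRBC2	C	TRB			true	M12888;L36092
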