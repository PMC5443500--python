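# Haplogroup definition table for the horse mitochondrial d-loop classifier.
# Columns: name, position (1-based reference mitogenome), base (derived state),
# status in {mandatory, optional}.
# X4b and the hotspot list (15585, 15604, 15650, dismissed before matching)
# follow the published description: 15540 mandatory, 15718 optional, and
# 15495/15602/15720 characteristic (treated as optional here).
# The A/B/C/D/H/K/X3 entries are SYNTHETIC placeholders exercising the file
# format; replace them with the published definitions for real analyses.
name	position	base	status
__hotspots__	15585	.	hotspot
__hotspots__	15604	.	hotspot
__hotspots__	15650	.	hotspot
X4b	15540	T	mandatory
X4b	15495	G	optional
X4b	15602	C	optional
X4b	15718	A	optional
X4b	15720	G	optional
A	15597	T	mandatory
A	15635	G	optional
B	15534	A	mandatory
B	15496	T	optional
C	15617	T	mandatory
C	15738	C	optional
D	15703	A	mandatory
D	15553	G	optional
H	15667	C	mandatory
H	15711	T	optional
K	15740	G	mandatory
K	15577	A	optional
X3	15659	A	mandatory
X3	15726	T	optional
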