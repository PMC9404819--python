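# Default splice-signal base-frequency matrices (percent).
# donor: 9-mer spanning [-3,+6] around the exon|intron boundary (GT at +1,+2).
# acceptor: 14-mer spanning [-12,+2] (AG at -2,-1).
# Donor/acceptor values are assembled from the classic primate splice-site
# frequency compilations and are approximate; the branch_point matrix is a
# synthetic consensus-derived (yUnAy-style) stand-in. All three files are
# user-replaceable via load_splice_matrices(path).
kind	pos	A	C	G	T
donor	-3	33	37	18	12
donor	-2	61	11	12	16
donor	-1	10	3	80	7
donor	+1	0	0	100	0
donor	+2	0	0	0	100
donor	+3	53	3	42	2
donor	+4	71	8	12	9
donor	+5	7	6	81	6
donor	+6	16	16	22	46
acceptor	-12	11	31	11	47
acceptor	-11	10	33	10	47
acceptor	-10	10	31	10	49
acceptor	-9	9	33	9	49
acceptor	-8	10	35	10	45
acceptor	-7	9	38	9	44
acceptor	-6	9	41	8	42
acceptor	-5	9	44	7	40
acceptor	-4	24	28	6	42
acceptor	-3	4	74	1	21
acceptor	-2	100	0	0	0
acceptor	-1	0	0	100	0
acceptor	+1	25	15	50	10
acceptor	+2	22	22	22	34
branch_point	1	25	25	25	25
branch_point	2	15	30	15	40
branch_point	3	10	30	10	50
branch_point	4	15	20	40	25
branch_point	5	100	0	0	0
branch_point	6	5	40	10	45
branch_point	7	25	25	25	25
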