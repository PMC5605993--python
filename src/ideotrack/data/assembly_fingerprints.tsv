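# Assembly fingerprints: canonical chromosome lengths per supported build.
# Columns: assembly <TAB> label <TAB> length
# Lengths from the NCBI assembly reports for GRCh37 (GCA_000001405.1 /
# GCF_000001405.13) and GRCh38 (GCA_000001405.15 / GCF_000001405.26).
GRCh37	1	249250621
GRCh37	2	243199373
GRCh37	3	198022430
GRCh37	4	191154276
GRCh37	5	180915260
GRCh37	6	171115067
GRCh37	7	159138663
GRCh37	8	146364022
GRCh37	9	141213431
GRCh37	10	135534747
GRCh37	11	135006516
GRCh37	12	133851895
GRCh37	13	115169878
GRCh37	14	107349540
GRCh37	15	102531392
GRCh37	16	90354753
GRCh37	17	81195210
GRCh37	18	78077248
GRCh37	19	59128983
GRCh37	20	63025520
GRCh37	21	48129895
GRCh37	22	51304566
GRCh37	X	155270560
GRCh37	Y	59373566
GRCh37	MT	16569
GRCh38	1	248956422
GRCh38	2	242193529
GRCh38	3	198295559
GRCh38	4	190214555
GRCh38	5	181538259
GRCh38	6	170805979
GRCh38	7	159345973
GRCh38	8	145138636
GRCh38	9	138394717
GRCh38	10	133797422
GRCh38	11	135086622
GRCh38	12	133275309
GRCh38	13	114364328
GRCh38	14	107043718
GRCh38	15	101991189
GRCh38	16	90338345
GRCh38	17	83257441
GRCh38	18	80373285
GRCh38	19	58617616
GRCh38	20	64444167
GRCh38	21	46709983
GRCh38	22	50818468
GRCh38	X	156040895
GRCh38	Y	57227415
GRCh38	MT	16569
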