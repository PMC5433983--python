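site	river	position	A1	A2	A3	A4	A5	A6	A7	A8	total
BOW1	Bow	upstream	3	9	10	6	1	2	-	7	38
BOW7	Bow	downstream	2	7	11	6	-	-	-	8	34
OLD1	Oldman	upstream	1	11	8	7	-	4	-	9	40
OLD8	Oldman	downstream	4	15	4	8	1	-	-	6	38
MILK1	Milk	upstream	-	1	-	1	-	-	-	-	2
MILK2	Milk	downstream	1	2	12	15	-	-	5	1	36
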