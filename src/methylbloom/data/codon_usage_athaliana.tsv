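# Arabidopsis thaliana genome-wide codon usage, frequency per 1000 codons.
# Approximate representative values (athaliana-bundled-v1). This table is a
# replaceable default: supply your own two-column TSV for exact CAI work
# against a specific reference usage set.
TTT	21.8
TTC	20.6
TTA	12.6
TTG	20.9
CTT	24.5
CTC	16.1
CTA	9.9
CTG	9.7
ATT	21.5
ATC	18.5
ATA	12.6
ATG	24.5
GTT	27.2
GTC	12.8
GTA	9.9
GTG	17.4
TCT	25.2
TCC	11.2
TCA	18.3
TCG	9.3
CCT	18.7
CCC	5.3
CCA	16.1
CCG	8.6
ACT	17.5
ACC	10.3
ACA	15.7
ACG	7.7
GCT	28.3
GCC	10.3
GCA	17.5
GCG	9.0
TAT	14.6
TAC	13.7
TAA	0.9
TAG	0.5
CAT	13.8
CAC	8.7
CAA	19.4
CAG	15.2
AAT	22.3
AAC	20.9
AAA	30.8
AAG	32.7
GAT	36.6
GAC	17.2
GAA	34.3
GAG	32.2
TGT	10.5
TGC	7.2
TGA	1.2
TGG	12.5
CGT	9.0
CGC	3.8
CGA	6.3
CGG	4.9
AGT	14.0
AGC	11.3
AGA	19.0
AGG	11.0
GGT	22.2
GGC	9.2
GGA	24.2
GGG	10.2
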