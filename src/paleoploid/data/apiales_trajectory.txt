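# Apiales chromosome-evolution trajectory (synthetic transcription).
# The published trajectory is drawn pictorially; this script is an authored
# reconstruction constrained by everything the accompanying text states:
# 7 pre-triplication chromosomes E1-E7; 21 post-triplication chromosomes
# (A1-7, B1-7, C1-7) at node H; 8 chromosomes at node P before the
# Apiales-shared duplication; 10 at node Q before the Apiaceae-shared
# duplication; 11 proto-chromosomes at node R; P1 fused from A5+A1+A2;
# P7 a direct derivative of A7; Q2 formed by P7 and a P1 duplicate fusing
# between the two duplications; Q2a/Q2b crossovers contributing to R3, R4
# and R8.  Ancestral chromosomes are 100 gene-rank units each.
NODE E
WGT
REN E1a A1
REN E2a A2
REN E3a A3
REN E4a A4
REN E5a A5
REN E6a A6
REN E7a A7
REN E1b B1
REN E2b B2
REN E3b B3
REN E4b B4
REN E5b B5
REN E6b B6
REN E7b B7
REN E1c C1
REN E2c C2
REN E3c C3
REN E4c C4
REN E5c C5
REN E6c C6
REN E7c C7
NODE H
EJ A5 A1 -> P1I +S1
LOSS S1
EJ P1I A2 -> P1 +S2
LOSS S2
EJ B1 B2 -> P2 +S3
LOSS S3
EJ C1 C2 -> P3I +S4
LOSS S4
EJ P3I C3 -> P3 +S5
LOSS S5
EJ B3 B4 -> P4 +S6
LOSS S6
EJ A6 B5 -> P5 +S7
LOSS S7
EJ C4 C5 -> P6I +S8
LOSS S8
EJ P6I C6 -> P6II +S9
LOSS S9
EJ P6II C7 -> P6 +S10
LOSS S10
REN A7 P7
EJ A3 A4 -> P8I +S11
LOSS S11
EJ P8I B6 -> P8II +S12
LOSS S12
EJ P8II B7 -> P8 +S13
LOSS S13
NODE P
WGD
EJ P2a P3a -> Q1 +S14
LOSS S14
EJ P7a P1a -> Q2 +S15
LOSS S15
EJ P4a P5a -> Q3 +S16
LOSS S16
EJ P6a P8a -> Q4 +S17
LOSS S17
EJ P1b P2b -> Q5 +S18
LOSS S18
EJ P3b P4b -> Q9 +S19
LOSS S19
REN P5b Q6
REN P6b Q7
REN P7b Q8
REN P8b Q10
NODE Q
WGD
EJ Q1a Q3a -> R1I +S20
LOSS S20
EJ Q6a Q7a -> R4I +S21
LOSS S21
EJ Q4a Q5a -> R5 +S22
LOSS S22
EJ Q8a Q10a -> R6 +S23
LOSS S23
EJ Q1b Q4b -> R7 +S24
LOSS S24
EJ Q3b Q5b -> R9 +S25
LOSS S25
EJ Q6b Q8b -> R10 +S26
LOSS S26
EJ Q7b Q10b -> R11 +S27
LOSS S27
EJ Q9a R1I -> R1 +S28
LOSS S28
X Q2a@200 R4I@300 -> R4 R2
X Q2b@150 Q9b@250 -> R3 R8
INV R1 50..250
NODE R
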