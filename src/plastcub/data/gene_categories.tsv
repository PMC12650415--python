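gene	category
psaA	photosynthesis
psaB	photosynthesis
psaC	photosynthesis
psaI	photosynthesis
psaJ	photosynthesis
psbA	photosynthesis
psbB	photosynthesis
psbC	photosynthesis
psbD	photosynthesis
psbE	photosynthesis
psbF	photosynthesis
psbH	photosynthesis
psbI	photosynthesis
psbJ	photosynthesis
psbK	photosynthesis
psbL	photosynthesis
psbM	photosynthesis
psbN	photosynthesis
psbT	photosynthesis
psbZ	photosynthesis
petA	photosynthesis
petB	photosynthesis
petD	photosynthesis
petG	photosynthesis
petL	photosynthesis
petN	photosynthesis
atpA	photosynthesis
atpB	photosynthesis
atpE	photosynthesis
atpF	photosynthesis
atpH	photosynthesis
atpI	photosynthesis
ndhA	photosynthesis
ndhB	photosynthesis
ndhC	photosynthesis
ndhD	photosynthesis
ndhE	photosynthesis
ndhF	photosynthesis
ndhG	photosynthesis
ndhH	photosynthesis
ndhI	photosynthesis
ndhJ	photosynthesis
ndhK	photosynthesis
rbcL	photosynthesis
rps2	self-replication
rps3	self-replication
rps4	self-replication
rps7	self-replication
rps8	self-replication
rps11	self-replication
rps12	self-replication
rps14	self-replication
rps15	self-replication
rps16	self-replication
rps18	self-replication
rps19	self-replication
rpl2	self-replication
rpl14	self-replication
rpl16	self-replication
rpl20	self-replication
rpl22	self-replication
rpl23	self-replication
rpl32	self-replication
rpl33	self-replication
rpl36	self-replication
rpoA	self-replication
rpoB	self-replication
rpoC1	self-replication
rpoC2	self-replication
infA	self-replication
matK	other
ccsA	other
cemA	other
accD	other
clpP	other
ycf1	other
ycf2	other
ycf3	other
ycf4	other
ycf15	other
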