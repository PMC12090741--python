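gene_id	pathway
amyX	C_hydrolysis
apu	C_hydrolysis
amyA	C_hydrolysis
sga	C_hydrolysis
abfA	C_hydrolysis
manB	C_hydrolysis
xylA	C_hydrolysis
cdh	C_hydrolysis
cex	C_hydrolysis
naglu	C_hydrolysis
chiA	C_hydrolysis
exo-chi	C_hydrolysis
pgu	C_hydrolysis
glx	C_hydrolysis
lig	C_hydrolysis
mnp	C_hydrolysis
pox	C_hydrolysis
napA	N_transformation
gdhA	N_transformation
nasA	N_transformation
nirK1	N_transformation
nirK3	N_transformation
nirS2	N_transformation
nosZ1	N_transformation
narG	N_transformation
nirK2	N_transformation
nirS1	N_transformation
nirS3	N_transformation
nosZ2	N_transformation
nifH	N_transformation
amoB	N_transformation
amoA1	N_transformation
nxrA	N_transformation
hao	N_transformation
amoA2	N_transformation
ureC	N_transformation
hzo	N_transformation
hzsA	N_transformation
hzsB	N_transformation
phoD	P_solubilization
cphy	P_solubilization
bpp	P_solubilization
phoX	P_solubilization
phnK	P_solubilization
pqqC	P_solubilization
gcd	P_solubilization
ppk	P_solubilization
ppx	P_solubilization
cbbL	other
mcrA	other
pmoA	other
mxaF	other
cdaR	other
glp	other
invA	other
cellobiase	other
vanA	other
frdA	other
fungcbhIR	other
lip	other
phnA	other
nirA	other
norB1	other
norB2	other
qnorB	other
pcc	other
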