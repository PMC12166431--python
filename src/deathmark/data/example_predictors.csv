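Gene,Inducer 1 AUC cor to expression,Inducer 2 AUC cor to expression,Inducer 1 AUC cor to depscore,Inducer 2 AUC cor to depscore,Transcriptomic similarity to HCC70 treated with inducer 1,Transcriptomic similarity to HCC70 treated with inducer 2,Transcriptomic similarity to BT549 treated with inducer 1,Transcriptomic similarity to BT549 treated with inducer 2
CYP1B1,-0.279,-0.234,-0.049,-0.102,-3783,1074,-35,-1640
ZNF180,0.014,-0.178,-0.444,-0.535,-3700,959,114,-1210
CLK1,-0.222,-0.355,-0.307,-0.318,-3652,-1115,-393,-2012
SLC25A46,-0.565,-0.615,-0.457,-0.398,-3621,-2850,-2886,-876
RPTOR,-0.074,0.063,0.012,0.028,-3441,4246,2930,20
PDLIM1,-0.418,-0.445,-0.330,-0.275,-3417,-1830,-198,-118
BAZ1B,-0.316,-0.108,0.097,0.010,-3387,1970,1896,7431
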