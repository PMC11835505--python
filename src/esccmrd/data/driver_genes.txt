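# Default driver-gene list for tumor-informed ctDNA tracking in ESCC.
# One symbol per line; override with --drivers / TrackingConfig.driver_genes.
TP53
KMT2D
NOTCH1
CCND1
MYC
PIK3CA
NFE2L2
CDKN2A
FAT1
EP300
KDM6A
RB1
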