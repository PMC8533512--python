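journal	impact_factor
Nature Communications	11.9
Journal of Immunology	4.7
Frontiers in Immunology	5.1
Glia	5.9
Cells	4.4
Nature	42.8
Science	41.8
Cell	38.6
PLOS ONE	2.7
Scientific Reports	4.0
J Immunol	4.7
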