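population	culinaris	orientalis	nigricans	odemensis	ervoides	tomentosus
culinaris	0
orientalis	0.1462	0
nigricans	0.3357	0.3364	0
odemensis	0.364	0.3917	0.3798	0
ervoides	0.3574	0.3996	0.3311	0.2364	0
tomentosus	0.6456	0.6469	0.7143	0.6515	0.5431	0
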