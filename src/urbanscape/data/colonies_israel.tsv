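colony_id	lat	lon	group	urban_cover_pct
herzliya_cave	32.168	34.814	urban	64.5
halfred_bridge	32.093	34.801	urban	89.4
dan_center_ramat_gan	32.092	34.822	urban	85.8
soncino_tel_aviv	32.066	34.787	urban	87.6
jaffa_soap_factory	32.054	34.754	urban	90.9
twins_cave	31.726	35.020	rural	13.1
sgafim_cave	31.682	34.909	rural	6.4
luzit_cave	31.675	34.885	rural	2.9
beit_guvrin_cave	31.600	34.902	rural	2.9
semech_cave	31.555	34.812	rural	13.1
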