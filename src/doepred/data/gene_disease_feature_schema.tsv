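feature_name	group	af_bin	direction
eqtl_inhibitor	common	common	concordance_inhibitor
eqtl_activator	common	common	concordance_activator
l2g_inhibitor	common	common	concordance_inhibitor
l2g_activator	common	common	concordance_activator
rare_finngen_gof	rare	rare	gof_like
rare_finngen_lof_hc	rare	rare	lof_like
rare_finngen_lof_lc	rare	rare	lof_like
rare_finngen_missense_del	rare	rare	lof_like
rare_finngen_missense_ben	rare	rare	none
rare_finngen_other	rare	rare	none
rare_finngen_unknown	rare	rare	none
rare_genebass_gof	rare	rare	gof_like
rare_genebass_lof_hc	rare	rare	lof_like
rare_genebass_lof_lc	rare	rare	lof_like
rare_genebass_missense_del	rare	rare	lof_like
rare_genebass_missense_ben	rare	rare	none
rare_genebass_other	rare	rare	none
rare_genebass_unknown	rare	rare	none
burden_finngen_plof	burden	ultrarare	lof_like
burden_finngen_missense	burden	ultrarare	lof_like
burden_finngen_plof_missense	burden	ultrarare	lof_like
burden_genebass_plof	burden	ultrarare	lof_like
burden_genebass_missense	burden	ultrarare	lof_like
burden_genebass_plof_missense	burden	ultrarare	lof_like
burden_jurgens_plof	burden	ultrarare	lof_like
burden_jurgens_missense	burden	ultrarare	lof_like
burden_jurgens_plof_missense	burden	ultrarare	lof_like
clinical_gof	complementary	none	gof_like
clinical_lof	complementary	none	lof_like
mouse_ko_direction	complementary	none	lof_like
expression_direction	complementary	none	gof_like
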