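name	kind
loeuf	continuous
missense_oe	continuous
synonymous_oe	continuous
haploinsufficiency_pred	continuous
triplosensitivity_pred	continuous
tau_tissue_specificity	continuous
median_tpm_log	continuous
expression_breadth	continuous
antibody_count_log	continuous
pocket_count	continuous
pocket_max_druggability	continuous
ppi_degree_log	continuous
paralog_count	continuous
gene_length_log	continuous
exon_count	continuous
protein_length_log	continuous
isoform_count	continuous
transmembrane_helix_count	continuous
ot_tractability_sm	continuous
ot_tractability_ab	continuous
ot_safety_event_count	continuous
depmap_common_essential	binary
depmap_strongly_selective	binary
oncokb_oncogene	binary
oncokb_tsg	binary
omim_autosomal_dominant	binary
omim_autosomal_recessive	binary
clingen_haploinsufficient	binary
gofcards_gof	binary
predicted_gof_mechanism	binary
predicted_lof_mechanism	binary
predicted_dn_mechanism	binary
hpa_membrane	binary
hpa_secreted	binary
hpa_nuclear	binary
hpa_enzyme	binary
hpa_gpcr	binary
hpa_transcription_factor	binary
hpa_transporter	binary
hpa_ion_channel	binary
signal_peptide	binary
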