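Genu_of_corpus_callosum
Body_of_corpus_callosum
Splenium_of_corpus_callosum
Fornix_column_and_body
Corticospinal_tract_R
Corticospinal_tract_L
Medial_lemniscus_R
Medial_lemniscus_L
Inferior_cerebellar_peduncle_R
Inferior_cerebellar_peduncle_L
Superior_cerebellar_peduncle_R
Superior_cerebellar_peduncle_L
Cerebral_peduncle_R
Cerebral_peduncle_L
Anterior_limb_of_internal_capsule_R
Anterior_limb_of_internal_capsule_L
Posterior_limb_of_internal_capsule_R
Posterior_limb_of_internal_capsule_L
Retrolenticular_part_of_internal_capsule_R
Retrolenticular_part_of_internal_capsule_L
Anterior_corona_radiata_R
Anterior_corona_radiata_L
Superior_corona_radiata_R
Superior_corona_radiata_L
Posterior_corona_radiata_R
Posterior_corona_radiata_L
Posterior_thalamic_radiation_R
Posterior_thalamic_radiation_L
Sagittal_stratum_R
Sagittal_stratum_L
External_capsule_R
External_capsule_L
Cingulum_cingulate_gyrus_R
Cingulum_cingulate_gyrus_L
Cingulum_hippocampus_R
Cingulum_hippocampus_L
Fornix_cres_Stria_terminalis_R
Fornix_cres_Stria_terminalis_L
Superior_longitudinal_fasciculus_R
Superior_longitudinal_fasciculus_L
Superior_fronto-occipital_fasciculus_R
Superior_fronto-occipital_fasciculus_L
Uncinate_fasciculus_R
Uncinate_fasciculus_L
Tapetum_R
Tapetum_L
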