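{
 "version": "1.0",
 "description": "Canonical whole-brain parcellation of 83 regions with hemisphere suffixes (_L/_R); midline structures carry no suffix. gm_exempt lists the 18 regions whose volumes are taken as full-structure volumes rather than grey-matter portions: ventricular regions and corpus callosum contain no grey matter, and deep grey nuclei (caudate, accumbens, putamen, pallidum, substantia nigra, thalamus) plus brainstem are typically assigned <=50% grey-matter probability by tissue segmentation. The midline third ventricle is left under the standard masking rule so that the exemption list comprises exactly 18 entries; this enumeration is one consistent choice among several.",
 "names": [
  "Hippocampus_L",
  "Hippocampus_R",
  "Amygdala_L",
  "Amygdala_R",
  "Ant_temporal_lobe_medial_L",
  "Ant_temporal_lobe_medial_R",
  "Ant_temporal_lobe_lateral_L",
  "Ant_temporal_lobe_lateral_R",
  "Parahippocampal_gyrus_L",
  "Parahippocampal_gyrus_R",
  "Sup_temporal_gyrus_post_L",
  "Sup_temporal_gyrus_post_R",
  "Sup_temporal_gyrus_ant_L",
  "Sup_temporal_gyrus_ant_R",
  "Mid_inf_temporal_gyrus_L",
  "Mid_inf_temporal_gyrus_R",
  "Fusiform_gyrus_L",
  "Fusiform_gyrus_R",
  "Post_temporal_lobe_L",
  "Post_temporal_lobe_R",
  "Cerebellum_L",
  "Cerebellum_R",
  "Brainstem",
  "Insula_L",
  "Insula_R",
  "Ant_cingulate_gyrus_L",
  "Ant_cingulate_gyrus_R",
  "Post_cingulate_gyrus_L",
  "Post_cingulate_gyrus_R",
  "Mid_frontal_gyrus_L",
  "Mid_frontal_gyrus_R",
  "Precentral_gyrus_L",
  "Precentral_gyrus_R",
  "Straight_gyrus_L",
  "Straight_gyrus_R",
  "Ant_orbital_gyrus_L",
  "Ant_orbital_gyrus_R",
  "Inf_frontal_gyrus_L",
  "Inf_frontal_gyrus_R",
  "Sup_frontal_gyrus_L",
  "Sup_frontal_gyrus_R",
  "Med_orbital_gyrus_L",
  "Med_orbital_gyrus_R",
  "Lat_orbital_gyrus_L",
  "Lat_orbital_gyrus_R",
  "Post_orbital_gyrus_L",
  "Post_orbital_gyrus_R",
  "Subgenual_frontal_cortex_L",
  "Subgenual_frontal_cortex_R",
  "Subcallosal_area_L",
  "Subcallosal_area_R",
  "Presubgenual_frontal_cortex_L",
  "Presubgenual_frontal_cortex_R",
  "Postcentral_gyrus_L",
  "Postcentral_gyrus_R",
  "Sup_parietal_gyrus_L",
  "Sup_parietal_gyrus_R",
  "Inf_lat_parietal_lobe_L",
  "Inf_lat_parietal_lobe_R",
  "Lingual_gyrus_L",
  "Lingual_gyrus_R",
  "Cuneus_L",
  "Cuneus_R",
  "Lat_occipital_lobe_L",
  "Lat_occipital_lobe_R",
  "Caudate_nucleus_L",
  "Caudate_nucleus_R",
  "Nucleus_accumbens_L",
  "Nucleus_accumbens_R",
  "Putamen_L",
  "Putamen_R",
  "Thalamus_L",
  "Thalamus_R",
  "Pallidum_L",
  "Pallidum_R",
  "Substantia_nigra_L",
  "Substantia_nigra_R",
  "Corpus_callosum",
  "Lat_ventricle_L",
  "Lat_ventricle_R",
  "Lat_ventricle_temporal_horn_L",
  "Lat_ventricle_temporal_horn_R",
  "Third_ventricle"
 ],
 "gm_exempt": [
  "Caudate_nucleus_L",
  "Caudate_nucleus_R",
  "Nucleus_accumbens_L",
  "Nucleus_accumbens_R",
  "Putamen_L",
  "Putamen_R",
  "Thalamus_L",
  "Thalamus_R",
  "Pallidum_L",
  "Pallidum_R",
  "Substantia_nigra_L",
  "Substantia_nigra_R",
  "Lat_ventricle_L",
  "Lat_ventricle_R",
  "Lat_ventricle_temporal_horn_L",
  "Lat_ventricle_temporal_horn_R",
  "Corpus_callosum",
  "Brainstem"
 ],
 "lobes": {
  "Hippocampus_L": "temporal",
  "Hippocampus_R": "temporal",
  "Amygdala_L": "temporal",
  "Amygdala_R": "temporal",
  "Ant_temporal_lobe_medial_L": "temporal",
  "Ant_temporal_lobe_medial_R": "temporal",
  "Ant_temporal_lobe_lateral_L": "temporal",
  "Ant_temporal_lobe_lateral_R": "temporal",
  "Parahippocampal_gyrus_L": "temporal",
  "Parahippocampal_gyrus_R": "temporal",
  "Sup_temporal_gyrus_post_L": "temporal",
  "Sup_temporal_gyrus_post_R": "temporal",
  "Sup_temporal_gyrus_ant_L": "temporal",
  "Sup_temporal_gyrus_ant_R": "temporal",
  "Mid_inf_temporal_gyrus_L": "temporal",
  "Mid_inf_temporal_gyrus_R": "temporal",
  "Fusiform_gyrus_L": "temporal",
  "Fusiform_gyrus_R": "temporal",
  "Post_temporal_lobe_L": "temporal",
  "Post_temporal_lobe_R": "temporal",
  "Cerebellum_L": "posterior_fossa",
  "Cerebellum_R": "posterior_fossa",
  "Brainstem": "posterior_fossa",
  "Insula_L": "insula_cingulate",
  "Insula_R": "insula_cingulate",
  "Ant_cingulate_gyrus_L": "insula_cingulate",
  "Ant_cingulate_gyrus_R": "insula_cingulate",
  "Post_cingulate_gyrus_L": "insula_cingulate",
  "Post_cingulate_gyrus_R": "insula_cingulate",
  "Mid_frontal_gyrus_L": "frontal",
  "Mid_frontal_gyrus_R": "frontal",
  "Precentral_gyrus_L": "frontal",
  "Precentral_gyrus_R": "frontal",
  "Straight_gyrus_L": "frontal",
  "Straight_gyrus_R": "frontal",
  "Ant_orbital_gyrus_L": "frontal",
  "Ant_orbital_gyrus_R": "frontal",
  "Inf_frontal_gyrus_L": "frontal",
  "Inf_frontal_gyrus_R": "frontal",
  "Sup_frontal_gyrus_L": "frontal",
  "Sup_frontal_gyrus_R": "frontal",
  "Med_orbital_gyrus_L": "frontal",
  "Med_orbital_gyrus_R": "frontal",
  "Lat_orbital_gyrus_L": "frontal",
  "Lat_orbital_gyrus_R": "frontal",
  "Post_orbital_gyrus_L": "frontal",
  "Post_orbital_gyrus_R": "frontal",
  "Subgenual_frontal_cortex_L": "frontal",
  "Subgenual_frontal_cortex_R": "frontal",
  "Subcallosal_area_L": "frontal",
  "Subcallosal_area_R": "frontal",
  "Presubgenual_frontal_cortex_L": "frontal",
  "Presubgenual_frontal_cortex_R": "frontal",
  "Postcentral_gyrus_L": "parietal",
  "Postcentral_gyrus_R": "parietal",
  "Sup_parietal_gyrus_L": "parietal",
  "Sup_parietal_gyrus_R": "parietal",
  "Inf_lat_parietal_lobe_L": "parietal",
  "Inf_lat_parietal_lobe_R": "parietal",
  "Lingual_gyrus_L": "occipital",
  "Lingual_gyrus_R": "occipital",
  "Cuneus_L": "occipital",
  "Cuneus_R": "occipital",
  "Lat_occipital_lobe_L": "occipital",
  "Lat_occipital_lobe_R": "occipital",
  "Caudate_nucleus_L": "central",
  "Caudate_nucleus_R": "central",
  "Nucleus_accumbens_L": "central",
  "Nucleus_accumbens_R": "central",
  "Putamen_L": "central",
  "Putamen_R": "central",
  "Thalamus_L": "central",
  "Thalamus_R": "central",
  "Pallidum_L": "central",
  "Pallidum_R": "central",
  "Substantia_nigra_L": "central",
  "Substantia_nigra_R": "central",
  "Corpus_callosum": "central",
  "Lat_ventricle_L": "ventricular",
  "Lat_ventricle_R": "ventricular",
  "Lat_ventricle_temporal_horn_L": "ventricular",
  "Lat_ventricle_temporal_horn_R": "ventricular",
  "Third_ventricle": "ventricular"
 }
}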