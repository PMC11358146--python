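# Heuristic, name-based assignment of 105 Harvard-Oxford-style cortical/subcortical
# ROI labels to the 7 Yeo resting-state networks (synthetic mapping shipped as a
# convenience fixture; supply your own winner-take-all atlas mapping for real data).
roi_name	network
Frontal Pole L	frontoparietal
Frontal Pole R	frontoparietal
Insular Cortex L	ventral_attention
Insular Cortex R	ventral_attention
Superior Frontal Gyrus L	default_mode
Superior Frontal Gyrus R	default_mode
Middle Frontal Gyrus L	frontoparietal
Middle Frontal Gyrus R	frontoparietal
Inferior Frontal Gyrus pars triangularis L	frontoparietal
Inferior Frontal Gyrus pars triangularis R	frontoparietal
Inferior Frontal Gyrus pars opercularis L	frontoparietal
Inferior Frontal Gyrus pars opercularis R	frontoparietal
Precentral Gyrus L	somatomotor
Precentral Gyrus R	somatomotor
Temporal Pole L	limbic
Temporal Pole R	limbic
Superior Temporal Gyrus anterior L	somatomotor
Superior Temporal Gyrus anterior R	somatomotor
Superior Temporal Gyrus posterior L	somatomotor
Superior Temporal Gyrus posterior R	somatomotor
Middle Temporal Gyrus anterior L	default_mode
Middle Temporal Gyrus anterior R	default_mode
Middle Temporal Gyrus posterior L	default_mode
Middle Temporal Gyrus posterior R	default_mode
Middle Temporal Gyrus temporooccipital L	dorsal_attention
Middle Temporal Gyrus temporooccipital R	dorsal_attention
Inferior Temporal Gyrus anterior L	default_mode
Inferior Temporal Gyrus anterior R	default_mode
Inferior Temporal Gyrus posterior L	default_mode
Inferior Temporal Gyrus posterior R	default_mode
Inferior Temporal Gyrus temporooccipital L	dorsal_attention
Inferior Temporal Gyrus temporooccipital R	dorsal_attention
Postcentral Gyrus L	somatomotor
Postcentral Gyrus R	somatomotor
Superior Parietal Lobule L	dorsal_attention
Superior Parietal Lobule R	dorsal_attention
Supramarginal Gyrus anterior L	ventral_attention
Supramarginal Gyrus anterior R	ventral_attention
Supramarginal Gyrus posterior L	ventral_attention
Supramarginal Gyrus posterior R	ventral_attention
Angular Gyrus L	default_mode
Angular Gyrus R	default_mode
Lateral Occipital Cortex superior L	dorsal_attention
Lateral Occipital Cortex superior R	dorsal_attention
Lateral Occipital Cortex inferior L	visual
Lateral Occipital Cortex inferior R	visual
Intracalcarine Cortex L	visual
Intracalcarine Cortex R	visual
Frontal Medial Cortex L	default_mode
Frontal Medial Cortex R	default_mode
Juxtapositional Lobule (SMA) L	somatomotor
Juxtapositional Lobule (SMA) R	somatomotor
Subcallosal Cortex L	limbic
Subcallosal Cortex R	limbic
Paracingulate Gyrus L	default_mode
Paracingulate Gyrus R	default_mode
Cingulate Gyrus anterior L	ventral_attention
Cingulate Gyrus anterior R	ventral_attention
Cingulate Gyrus posterior L	default_mode
Cingulate Gyrus posterior R	default_mode
Precuneous Cortex L	default_mode
Precuneous Cortex R	default_mode
Cuneal Cortex L	visual
Cuneal Cortex R	visual
Frontal Orbital Cortex L	limbic
Frontal Orbital Cortex R	limbic
Parahippocampal Gyrus anterior L	limbic
Parahippocampal Gyrus anterior R	limbic
Parahippocampal Gyrus posterior L	limbic
Parahippocampal Gyrus posterior R	limbic
Lingual Gyrus L	visual
Lingual Gyrus R	visual
Temporal Fusiform Cortex anterior L	limbic
Temporal Fusiform Cortex anterior R	limbic
Temporal Fusiform Cortex posterior L	default_mode
Temporal Fusiform Cortex posterior R	default_mode
Temporal Occipital Fusiform Cortex L	dorsal_attention
Temporal Occipital Fusiform Cortex R	dorsal_attention
Occipital Fusiform Gyrus L	visual
Occipital Fusiform Gyrus R	visual
Frontal Operculum Cortex L	ventral_attention
Frontal Operculum Cortex R	ventral_attention
Central Opercular Cortex L	somatomotor
Central Opercular Cortex R	somatomotor
Parietal Operculum Cortex L	ventral_attention
Parietal Operculum Cortex R	ventral_attention
Planum Polare L	somatomotor
Planum Polare R	somatomotor
Heschl's Gyrus L	somatomotor
Heschl's Gyrus R	somatomotor
Planum Temporale L	somatomotor
Planum Temporale R	somatomotor
Supracalcarine Cortex L	visual
Supracalcarine Cortex R	visual
Occipital Pole L	visual
Occipital Pole R	visual
Thalamus L	ventral_attention
Thalamus R	ventral_attention
Caudate L	frontoparietal
Caudate R	frontoparietal
Putamen L	somatomotor
Putamen R	somatomotor
Hippocampus L	limbic
Hippocampus R	limbic
Brainstem	somatomotor
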