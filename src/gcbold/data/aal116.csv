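name,hemisphere,lobe
Precentral_L,L,frontal
Precentral_R,R,frontal
Frontal_Sup_L,L,frontal
Frontal_Sup_R,R,frontal
Frontal_Sup_Orb_L,L,frontal
Frontal_Sup_Orb_R,R,frontal
Frontal_Mid_L,L,frontal
Frontal_Mid_R,R,frontal
Frontal_Mid_Orb_L,L,frontal
Frontal_Mid_Orb_R,R,frontal
Frontal_Inf_Oper_L,L,frontal
Frontal_Inf_Oper_R,R,frontal
Frontal_Inf_Tri_L,L,frontal
Frontal_Inf_Tri_R,R,frontal
Frontal_Inf_Orb_L,L,frontal
Frontal_Inf_Orb_R,R,frontal
Rolandic_Oper_L,L,frontal
Rolandic_Oper_R,R,frontal
Supp_Motor_Area_L,L,frontal
Supp_Motor_Area_R,R,frontal
Olfactory_L,L,frontal
Olfactory_R,R,frontal
Frontal_Sup_Medial_L,L,frontal
Frontal_Sup_Medial_R,R,frontal
Frontal_Med_Orb_L,L,frontal
Frontal_Med_Orb_R,R,frontal
Rectus_L,L,frontal
Rectus_R,R,frontal
Insula_L,L,insula
Insula_R,R,insula
Cingulum_Ant_L,L,limbic
Cingulum_Ant_R,R,limbic
Cingulum_Mid_L,L,limbic
Cingulum_Mid_R,R,limbic
Cingulum_Post_L,L,limbic
Cingulum_Post_R,R,limbic
Hippocampus_L,L,limbic
Hippocampus_R,R,limbic
ParaHippocampal_L,L,limbic
ParaHippocampal_R,R,limbic
Amygdala_L,L,limbic
Amygdala_R,R,limbic
Calcarine_L,L,occipital
Calcarine_R,R,occipital
Cuneus_L,L,occipital
Cuneus_R,R,occipital
Lingual_L,L,occipital
Lingual_R,R,occipital
Occipital_Sup_L,L,occipital
Occipital_Sup_R,R,occipital
Occipital_Mid_L,L,occipital
Occipital_Mid_R,R,occipital
Occipital_Inf_L,L,occipital
Occipital_Inf_R,R,occipital
Fusiform_L,L,temporal
Fusiform_R,R,temporal
Postcentral_L,L,parietal
Postcentral_R,R,parietal
Parietal_Sup_L,L,parietal
Parietal_Sup_R,R,parietal
Parietal_Inf_L,L,parietal
Parietal_Inf_R,R,parietal
SupraMarginal_L,L,parietal
SupraMarginal_R,R,parietal
Angular_L,L,parietal
Angular_R,R,parietal
Precuneus_L,L,parietal
Precuneus_R,R,parietal
Paracentral_Lobule_L,L,parietal
Paracentral_Lobule_R,R,parietal
Caudate_L,L,subcortical
Caudate_R,R,subcortical
Putamen_L,L,subcortical
Putamen_R,R,subcortical
Pallidum_L,L,subcortical
Pallidum_R,R,subcortical
Thalamus_L,L,subcortical
Thalamus_R,R,subcortical
Heschl_L,L,temporal
Heschl_R,R,temporal
Temporal_Sup_L,L,temporal
Temporal_Sup_R,R,temporal
Temporal_Pole_Sup_L,L,temporal
Temporal_Pole_Sup_R,R,temporal
Temporal_Mid_L,L,temporal
Temporal_Mid_R,R,temporal
Temporal_Pole_Mid_L,L,temporal
Temporal_Pole_Mid_R,R,temporal
Temporal_Inf_L,L,temporal
Temporal_Inf_R,R,temporal
Cerebelum_Crus1_L,L,cerebellum
Cerebelum_Crus1_R,R,cerebellum
Cerebelum_Crus2_L,L,cerebellum
Cerebelum_Crus2_R,R,cerebellum
Cerebelum_3_L,L,cerebellum
Cerebelum_3_R,R,cerebellum
Cerebelum_4_5_L,L,cerebellum
Cerebelum_4_5_R,R,cerebellum
Cerebelum_6_L,L,cerebellum
Cerebelum_6_R,R,cerebellum
Cerebelum_7b_L,L,cerebellum
Cerebelum_7b_R,R,cerebellum
Cerebelum_8_L,L,cerebellum
Cerebelum_8_R,R,cerebellum
Cerebelum_9_L,L,cerebellum
Cerebelum_9_R,R,cerebellum
Cerebelum_10_L,L,cerebellum
Cerebelum_10_R,R,cerebellum
Vermis_1_2,M,vermis
Vermis_3,M,vermis
Vermis_4_5,M,vermis
Vermis_6,M,vermis
Vermis_7,M,vermis
Vermis_8,M,vermis
Vermis_9,M,vermis
Vermis_10,M,vermis
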