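label,x,y,z
Precentral_L,-39,-6,51
Precentral_R,41,-8,52
Frontal_Sup_L,-18,35,42
Frontal_Sup_R,22,31,44
Frontal_Sup_Orb_L,-17,47,-13
Frontal_Sup_Orb_R,18,48,-14
Frontal_Mid_L,-33,33,35
Frontal_Mid_R,38,33,34
Frontal_Mid_Orb_L,-31,50,-10
Frontal_Mid_Orb_R,33,53,-11
Frontal_Inf_Oper_L,-48,13,19
Frontal_Inf_Oper_R,50,15,21
Frontal_Inf_Tri_L,-46,30,14
Frontal_Inf_Tri_R,50,30,14
Frontal_Inf_Orb_L,-36,31,-12
Frontal_Inf_Orb_R,41,32,-12
Rolandic_Oper_L,-47,-8,14
Rolandic_Oper_R,53,-6,15
Supp_Motor_Area_L,-5,5,61
Supp_Motor_Area_R,9,0,62
Olfactory_L,-8,15,-12
Olfactory_R,10,16,-11
Frontal_Sup_Medial_L,-5,49,31
Frontal_Sup_Medial_R,9,51,30
Frontal_Med_Orb_L,-5,54,-7
Frontal_Med_Orb_R,8,52,-7
Rectus_L,-5,37,-18
Rectus_R,8,36,-18
Insula_L,-35,7,3
Insula_R,39,6,2
Cingulum_Ant_L,-4,35,14
Cingulum_Ant_R,8,37,16
Cingulum_Mid_L,-5,-15,42
Cingulum_Mid_R,8,-9,40
Cingulum_Post_L,-5,-43,25
Cingulum_Post_R,7,-42,22
Hippocampus_L,-25,-21,-10
Hippocampus_R,29,-20,-10
ParaHippocampal_L,-21,-16,-21
ParaHippocampal_R,25,-15,-20
Amygdala_L,-23,-1,-17
Amygdala_R,27,1,-18
Calcarine_L,-7,-79,6
Calcarine_R,16,-73,9
Cuneus_L,-6,-80,27
Cuneus_R,14,-79,28
Lingual_L,-15,-68,-5
Lingual_R,16,-67,-4
Occipital_Sup_L,-17,-84,28
Occipital_Sup_R,24,-81,31
Occipital_Mid_L,-32,-81,16
Occipital_Mid_R,37,-80,19
Occipital_Inf_L,-36,-78,-8
Occipital_Inf_R,38,-82,-8
Fusiform_L,-31,-40,-20
Fusiform_R,34,-39,-20
Postcentral_L,-42,-23,49
Postcentral_R,41,-25,53
Parietal_Sup_L,-23,-60,59
Parietal_Sup_R,26,-59,62
Parietal_Inf_L,-43,-46,47
Parietal_Inf_R,46,-46,50
SupraMarginal_L,-56,-34,30
SupraMarginal_R,58,-32,34
Angular_L,-44,-61,36
Angular_R,46,-60,39
Precuneus_L,-7,-56,48
Precuneus_R,10,-56,44
Paracentral_Lobule_L,-8,-25,70
Paracentral_Lobule_R,7,-32,68
Caudate_L,-11,11,9
Caudate_R,15,12,9
Putamen_L,-24,4,2
Putamen_R,28,5,2
Pallidum_L,-18,0,0
Pallidum_R,21,0,0
Thalamus_L,-11,-18,8
Thalamus_R,13,-18,8
Heschl_L,-42,-19,10
Heschl_R,46,-17,10
Temporal_Sup_L,-53,-21,7
Temporal_Sup_R,58,-22,7
Temporal_Pole_Sup_L,-40,15,-20
Temporal_Pole_Sup_R,48,15,-17
Temporal_Mid_L,-56,-34,-2
Temporal_Mid_R,57,-37,-1
Temporal_Pole_Mid_L,-36,15,-34
Temporal_Pole_Mid_R,44,15,-32
Temporal_Inf_L,-50,-28,-23
Temporal_Inf_R,54,-31,-22
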