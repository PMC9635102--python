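candidate_id,name,indications,product_type,archetype,phase,last_activity_year,approved_for_indication,recommended_or_routine_use,recommended_for_subgroup_only,inactive_negative_outcome,targets_symptom_only,inferior_to_current,trial_settings,requires_cold_chain,on_who_eml,preclinical_subclass,evidence_concerns
CLN01,probiotic lactobacilli,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN02,vitamin D,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN03,omega-3 fatty acids,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN04,l-arginine,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN05,coenzyme Q10,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN06,dalteparin,prevention,drug,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN07,esomeprazole,prevention;treatment,drug,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN08,pravastatin,prevention;treatment,drug,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN09,selenium,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN10,vitamin B12,prevention,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN11,chloroquine/hydroxychloroquine,prevention,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN12,l-citrulline,prevention,dietary,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN13,dydrogesterone,prevention,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN14,metformin,prevention;treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN15,ozagrel,prevention;treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN16,pentaerythrityl tetranitrate,prevention,drug,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN17,salsalate,prevention,drug,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN18,sulforaphane,treatment,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN19,resveratrol,treatment,dietary,repurposed,III,2021,false,false,false,false,false,false,,unknown,false,,
CLN20,Curcuma longa,treatment,dietary,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN21,vitamin B3,treatment,dietary,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN22,serelaxin,treatment,biological,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN23,sildenafil citrate,treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN24,tadalafil,treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN25,rosuvastatin,treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN26,iloprost,treatment,drug,repurposed,II,2021,false,false,false,false,false,false,,unknown,false,,
CLN27,vardenafil,treatment,drug,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN28,Purnica granatum extract,treatment,dietary,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN29,sulfasalazine,treatment,drug,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN30,conestat alfa,treatment,biological,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN31,S-nitrosoglutathione,treatment,drug,repurposed,I,2021,false,false,false,false,false,false,,unknown,false,,
CLN32,RMC 035,treatment,biological,new,I,2021,false,false,false,false,false,false,,unknown,false,,
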