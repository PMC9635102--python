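candidate_id,name,indications,product_type,archetype,phase,last_activity_year,approved_for_indication,recommended_or_routine_use,recommended_for_subgroup_only,inactive_negative_outcome,targets_symptom_only,inferior_to_current,trial_settings,requires_cold_chain,on_who_eml,preclinical_subclass,evidence_concerns
PRE01,l-Ergothione,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE02,Hydrogen-rich saline,prevention,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,antioxidant,
PRE03,Simvastatin,prevention,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,enzyme inhibitors (statins),
PRE04,Lovastatin,prevention;treatment,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,enzyme inhibitors (statins),
PRE05,AP39,prevention;treatment,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,hydrogen sulphide donors,
PRE06,MZe786,prevention,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,hydrogen sulphide donors,
PRE07,Trehalose,prevention;treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,macronutrients,
PRE08,Grape seed extract,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE09,Mangiferin,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE10,Quercetin,prevention;treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE11,Scutellaria baicalensis root extract,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE12,Uncaria rhynchophylla extract,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE13,Vitexin,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE14,Vitis labrusca/vinifera extract,prevention,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,polyphenol,
PRE15,Ad-VEGF [viral vector delivery],prevention;treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,DNA/siRNA/mRNA,
PRE16,TRV027,prevention,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,small molecule,
PRE17,Cibinetide,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE18,Etanercept,treatment,biological,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE19,Liraglutide,treatment,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE20,Placental growth factor,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE21,SynB1-ELP-p50i [polypeptide delivery],treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE22,VEGF-B [polypeptide delivery],treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,amino acid-peptide,
PRE23,Ferulic acid,treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,antioxidant,
PRE24,HTHQ,treatment,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,antioxidant,
PRE25,MitoQ,treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,antioxidant,
PRE26,Emiplacel,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,cell therapy,
PRE27,Haemoglobin-vesicles [nanoparticle delivery],treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,cell therapy,
PRE28,Regulatory T cells,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,cell therapy,
PRE29,Euterpe oleracea,treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,herbal,
PRE30,Toki-shakuyaku-san,treatment,dietary,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,herbal,
PRE31,GYY4137,treatment,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,hydrogen sulphide donors,
PRE32,AGT-targeting siRNA,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,DNA/siRNA/mRNA,
PRE33,GPCR-AAB binding aptamers,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,DNA/siRNA/mRNA,
PRE34,sFlt-1-targeting siRNA,treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,DNA/siRNA/mRNA,
PRE35,sFlt-1-targeting siRNA [nanoparticle delivery],treatment,biological,new,preclinical,,false,false,false,false,false,false,,unknown,false,DNA/siRNA/mRNA,
PRE36,Gefitinib,treatment,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,small molecule,
PRE37,SB203580,treatment,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,small molecule,
PRE38,Sofalcone,treatment,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,small molecule,
PRE39,Carveol,treatment,drug,new,preclinical,,false,false,false,false,false,false,,unknown,false,vascular agents,
PRE40,Tetramethylpyrazine,treatment,drug,repurposed,preclinical,,false,false,false,false,false,false,,unknown,false,vascular agents,
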