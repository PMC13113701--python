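code,display_name,is_carbapenem,is_antipseudomonal,is_anti_mrsa,aware_class,ddd_ref_g,unit_cost_eur
AMOXICILLIN,Amoxicillin,0,0,0,ACCESS,1.5,0.90
AMOXICILLIN_CLAVULANATE,Amoxicillin/clavulanic acid,0,0,0,ACCESS,3.0,2.40
AMPICILLIN,Ampicillin (parenteral),0,0,0,ACCESS,6.0,3.60
AMPICILLIN_SULBACTAM,Ampicillin/sulbactam,0,0,0,ACCESS,6.0,5.20
BENZYLPENICILLIN,Benzylpenicillin,0,0,0,ACCESS,3.6,2.10
CEFUROXIME,Cefuroxime (parenteral),0,0,0,WATCH,3.0,3.90
CEFTRIAXONE,Ceftriaxone,0,0,0,WATCH,2.0,2.80
CEFOTAXIME,Cefotaxime,0,0,0,WATCH,4.0,4.50
CEFTAZIDIME,Ceftazidime,0,1,0,WATCH,4.0,9.60
CEFEPIME,Cefepime,0,1,0,WATCH,4.0,12.40
PIPERACILLIN_TAZOBACTAM,Piperacillin/tazobactam,0,1,0,WATCH,14.0,14.80
CEFTOLOZANE_TAZOBACTAM,Ceftolozane/tazobactam,0,1,0,RESERVE,3.0,210.00
AZTREONAM,Aztreonam,0,1,0,RESERVE,4.0,48.00
MEROPENEM,Meropenem,1,0,0,WATCH,3.0,21.30
IMIPENEM_CILASTATIN,Imipenem/cilastatin,1,0,0,WATCH,2.0,18.70
ERTAPENEM,Ertapenem,1,0,0,WATCH,1.0,32.50
VANCOMYCIN,Vancomycin (parenteral),0,0,1,WATCH,2.0,9.80
TEICOPLANIN,Teicoplanin,0,0,1,WATCH,0.4,17.40
LINEZOLID,Linezolid,0,0,1,RESERVE,1.2,58.00
DAPTOMYCIN,Daptomycin,0,0,1,RESERVE,0.28,96.00
CIPROFLOXACIN,Ciprofloxacin,0,0,0,WATCH,0.8,1.70
LEVOFLOXACIN,Levofloxacin,0,0,0,WATCH,0.5,2.30
MOXIFLOXACIN,Moxifloxacin,0,0,0,WATCH,0.4,4.10
AZITHROMYCIN,Azithromycin,0,0,0,WATCH,0.3,1.90
CLARITHROMYCIN,Clarithromycin,0,0,0,WATCH,1.0,2.60
DOXYCYCLINE,Doxycycline,0,0,0,ACCESS,0.1,0.60
GENTAMICIN,Gentamicin,0,0,0,ACCESS,0.24,1.40
AMIKACIN,Amikacin,0,0,0,ACCESS,1.0,3.80
METRONIDAZOLE,Metronidazole (parenteral),0,0,0,ACCESS,1.5,2.20
TRIMETHOPRIM_SULFAMETHOXAZOLE,Trimethoprim/sulfamethoxazole,0,0,0,ACCESS,1.92,1.10
NITROFURANTOIN,Nitrofurantoin,0,0,0,ACCESS,0.2,0.80
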