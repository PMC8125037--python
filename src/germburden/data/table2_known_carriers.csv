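case_id,predisposing_gene,nucleotide_change,amino_acid_change,mc1r_variants,sex,age_first_melanoma,n_melanoma,melanoma_histology,age_first_rcc,rcc_histology,other_solid_tumors,family_history
C001,MITF,c.952G>A,p.E318K,p.R163Q (r),M,33,2,SSM,27,chRCC,0,0
C002,MITF,c.952G>A,p.E318K,p.V92M (r),M,37,1,SSM,55,ccRCC,0,0
C003,MITF,c.952G>A,p.E318K,p.V60L (r);p.R160W (R),M,62,1,NM,51,ccRCC,0,0
C004,MITF,c.952G>A,p.E318K,WT,M,52,1,SSM,52,ccRCC,0,0
C005,MITF,c.952G>A,p.E318K,p.R160W (R);p.D294H (R),F,56,2,SSM,59,ccRCC,1,1
C006,MITF,c.952G>A,p.E318K,p.R163Q (r),M,60,1,SSM,60,chRCC,1,1
C007,MITF,c.952G>A,p.E318K,p.V60L (r),M,69,1,NM,69,ccRCC,0,0
C008,MITF,c.952G>A,p.E318K,p.R160W (R),M,75,2,NM,70,ccRCC,0,0
C009,MITF,c.952G>A,p.E318K,p.V92M (r);p.R151C (R),M,74,3,SSM,74,pRCC,1,1
C010,BAP1,c.37+1delG,p.?,p.V60L (r);p.R160W (R),F,29,6,SSM,49,ccRCC,0,1
C011,BAP1,c.78-79del,p.V27fs,WT,M,45,1,NM,53,ccRCC,0,1
C012,BAP1,c.1938T>A,p.Y646*,p.V60L (r),F,48,1,SSM,59,ccRCC,1,1
C013,CDKN2A,c.146T>G,p.I49S,p.V92M (r);p.R151C (R),F,31,1,SMM,36,ccRCC,0,1
C014,CDKN2A,c.159G>C,p.M53I,p.V60L (r);p.R151C (R),M,46,1,NM,61,ccRCC,0,1
C015,FLCN,c.663dupG,p.M222fs,WT,F,48,1,NM,43,chRCC,1,1
C016,FLCN,c.755dupC,p.C253fs,WT,M,64,1,SSM,62,ccRCC,1,0
C017,PTEN,c.959T>G,p.L320*,WT,F,55,1,SSM,55,ccRCC,0,1
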