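case_id,age_years,sex,af_duration_years,af_class,la_diameter_cm,lvef_pct,surface_cm2
1,46,F,1,PAF,3.4,70,259.4
2,70,M,3,PAF,3.9,55,296.1
3,48,M,5,PAF,3.7,60,271.4
4,69,F,1,PAF,3.8,55,303.3
5,44,F,1,PAF,3.9,60,286.5
6,72,M,3,PsAF,5.0,60,271.9
7,71,M,3,PsAF,3.9,65,439.2
8,61,M,1,PAF,4.5,60,285.1
9,73,F,6,PAF,3.1,60,276.3
10,48,M,2,PsAF,3.2,53,299.9
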