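participant_id,age,sex,time_since_stroke_months,stroke_type,vessels,hemisphere,slt,nbt,screeling_total
sub-006,86,m,22.8,ischemia,VA,bilateral,yes,263,70
sub-008,71,f,21.1,ischemia,MCA,left,no,273,69
sub-009,67,m,22.6,ischemia,MCA,left,no,262,65.5
sub-014,75,m,18.2,ischemia,MCA,left,yes,185,58
sub-016,68,m,18.0,ischemia,MCA,bilateral,yes,265,69
sub-017,88,m,8.2,ischemia,MCA/PCA,bilateral,no,245,56
sub-018,61,f,29.4,ischemia,MCA,left,yes,263,72
sub-019,72,m,8.6,ischemia,PCA,left,,211,51
sub-020,42,m,18.7,ischemia,MCA,left,yes,273,71
sub-021,81,m,8.6,hemorrhage,,left,no,252,70
sub-022,78,f,8.2,hemorrhage,,left,yes,207,56
sub-023,90,m,22.8,ischemia,LLA,bilateral,no,265,61
sub-024,69,m,6,ischemia,MCA,left,yes,260,68.5
sub-025,69,m,11.5,ischemia,MCA,left,yes,197,58.5
sub-026,71,m,31,ischemia,MCA,left,yes,250,69
sub-027,76,m,126.2,ischemia,MCA,left,yes,254,63
sub-028,80,m,25.2,ischemia,,left,no,195,54
sub-029,75,m,22.6,ischemia,MCA,left,yes,193,55
sub-030,49,m,13.1,hemorrhage,,left,yes,217,57
sub-031,79,m,12.9,ischemia,MCA,left,yes,263,63
sub-032,76,m,94.8,ischemia,MCA,left,yes,32,8
sub-034,79,m,13.4,,,,yes,244,69
sub-035,64,f,31.5,ischemia,MCA/ACA,left,yes,276,71
sub-038,60,f,368.6,,,,no,251,65
sub-049,85,f,8.3,ischemia,PICA,left,yes,242,65.5
sub-050,81,f,8.7,ischemia,MCA,left,yes,134,53
sub-052,72,m,120.7,,,,yes,175,48
sub-053,41,f,6.1,ischemia,MCA,left,yes,271,70
sub-054,69,m,17.2,ischemia,MCA,left,yes,268,69
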