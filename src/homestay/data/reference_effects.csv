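outcome,framing,term,beta,p
continuous,change_4h,NA,0.09,<.01
continuous,change_4h,NA×SIAS,-0.001,.98
continuous,change_4h,NA×DASS,-0.01,.81
continuous,change_4h,PA,-0.09,<.01
continuous,change_4h,PA×SIAS,0.01,.66
continuous,change_4h,PA×DASS,0.01,.85
continuous,same_day,NA,0.08,.02
continuous,same_day,NA×SIAS,-0.03,.31
continuous,same_day,NA×DASS,-0.40,.19
continuous,same_day,PA,0.05,.17
continuous,same_day,PA×SIAS,0.04,.23
continuous,same_day,PA×DASS,0.03,.27
continuous,prev_day,NA,0.03,.39
continuous,prev_day,NA×SIAS,-0.05,.19
continuous,prev_day,NA×DASS,-0.56,.11
continuous,prev_day,PA,-0.09,.02
continuous,prev_day,PA×SIAS,0.03,.40
continuous,prev_day,PA×DASS,0.05,.20
continuous,next_day,NA,-0.05,.12
continuous,next_day,NA×SIAS,-0.03,.37
continuous,next_day,NA×DASS,-0.01,.85
continuous,next_day,PA,0.09,<.01
continuous,next_day,PA×SIAS,0.004,.90
continuous,next_day,PA×DASS,-0.01,.67
binary,change_4h,NA,-0.02,.71
binary,change_4h,NA×SIAS,0.06,.15
binary,change_4h,NA×DASS,0.06,.25
binary,change_4h,PA,-0.03,.49
binary,change_4h,PA×SIAS,-0.03,.47
binary,change_4h,PA×DASS,-0.02,.76
binary,same_day,NA,0.01,.24
binary,same_day,NA×SIAS,-0.01,.29
binary,same_day,NA×DASS,-0.01,.42
binary,same_day,PA,-0.03,.01
binary,same_day,PA×SIAS,-0.01,.30
binary,same_day,PA×DASS,-0.001,.92
binary,prev_day,NA,-0.02,.27
binary,prev_day,NA×SIAS,0.01,.51
binary,prev_day,NA×DASS,0.01,.68
binary,prev_day,PA,-0.02,.37
binary,prev_day,PA×SIAS,-0.02,.22
binary,prev_day,PA×DASS,-0.03,.09
binary,next_day,NA,-0.01,.48
binary,next_day,NA×SIAS,0.05,<.01
binary,next_day,NA×DASS,0.02,.07
binary,next_day,PA,-0.01,.49
binary,next_day,PA×SIAS,-0.04,<.01
binary,next_day,PA×DASS,-0.01,.28
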