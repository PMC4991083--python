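sample_id,genotype,assay,replicate,ct
ctrl_0B_1,0B,target,1,27.05391103254547
ctrl_0B_1,0B,target,2,26.937666726470972
ctrl_0B_1,0B,target,3,26.843498727658933
ctrl_0B_1,0B,HPRT,1,26.984024541152813
ctrl_0B_1,0B,HPRT,2,26.42866239901866
ctrl_0B_1,0B,HPRT,3,27.179738309112548
ctrl_0B_2,0B,target,1,26.85836527498548
ctrl_0B_2,0B,target,2,26.516818719654594
ctrl_0B_2,0B,target,3,26.978920872596493
ctrl_0B_2,0B,HPRT,1,26.955008819672482
ctrl_0B_2,0B,HPRT,2,26.84668618588456
ctrl_0B_2,0B,HPRT,3,26.96001721477693
ctrl_0B_3,0B,target,1,27.07065771938939
ctrl_0B_3,0B,target,2,27.118350692963727
ctrl_0B_3,0B,target,3,27.204565950519328
ctrl_0B_3,0B,HPRT,1,27.101684798365685
ctrl_0B_3,0B,HPRT,2,26.988409383907722
ctrl_0B_3,0B,HPRT,3,27.033971304077813
ctrl_1B_1,1B,target,1,20.939324409124225
ctrl_1B_1,1B,target,2,21.073030807772163
ctrl_1B_1,1B,target,3,21.268674413176694
ctrl_1B_1,1B,HPRT,1,26.916537580835765
ctrl_1B_1,1B,HPRT,2,27.088753690940152
ctrl_1B_1,1B,HPRT,3,27.02516236662157
ctrl_1B_2,1B,target,1,21.04140310813492
ctrl_1B_2,1B,target,2,21.40091038818247
ctrl_1B_2,1B,target,3,20.84992483326691
ctrl_1B_2,1B,HPRT,1,26.697453091465796
ctrl_1B_2,1B,HPRT,2,26.8047808502099
ctrl_1B_2,1B,HPRT,3,26.93375125298504
ctrl_1B_3,1B,target,1,21.43170450678052
ctrl_1B_3,1B,target,2,21.179368872468434
ctrl_1B_3,1B,target,3,21.723871710668867
ctrl_1B_3,1B,HPRT,1,26.793668468441062
ctrl_1B_3,1B,HPRT,2,27.06013931313977
ctrl_1B_3,1B,HPRT,3,26.956025185766745
ctrl_2B_1,2B,target,1,20.34159464499437
ctrl_2B_1,2B,target,2,20.39835830661617
ctrl_2B_1,2B,target,3,20.412986103963963
ctrl_2B_1,2B,HPRT,1,26.913079111532515
ctrl_2B_1,2B,HPRT,2,27.188929549681617
ctrl_2B_1,2B,HPRT,3,27.169536273618856
ctrl_2B_2,2B,target,1,19.998542437016603
ctrl_2B_2,2B,target,2,20.510587520253207
ctrl_2B_2,2B,target,3,20.65010738251062
ctrl_2B_2,2B,HPRT,1,26.86404132110802
ctrl_2B_2,2B,HPRT,2,27.197052833419992
ctrl_2B_2,2B,HPRT,3,27.11122265302425
ctrl_2B_3,2B,target,1,20.334530299053803
ctrl_2B_3,2B,target,2,20.590971008011934
ctrl_2B_3,2B,target,3,20.337205549622098
ctrl_2B_3,2B,HPRT,1,26.8376205712953
ctrl_2B_3,2B,HPRT,2,26.876533481585597
ctrl_2B_3,2B,HPRT,3,27.175476608534094
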