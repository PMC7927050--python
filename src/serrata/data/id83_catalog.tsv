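Type	ID1	ID2	ID12
1:Del:C:0	0.0018606546	0.010840591	0.10044609
1:Del:C:1	0.0016156457	0.0044373895	0.00078103802
1:Del:C:2	0.0044649651	0.052120448	0.0056292858
1:Del:C:3	0.0015041507	0.050472757	0.00016829737
1:Del:C:4	0.0050315779	0.0025138318	0.0030855654
1:Del:C:5	0.012834147	0.0011513622	0.0032992133
1:Del:T:0	0.0010732434	0.0020400221	0.0088849747
1:Del:T:1	0.0047797597	0.0044321843	0.0010303171
1:Del:T:2	0.0017534195	0.00051058437	0.0031010502
1:Del:T:3	0.0042842028	0.15384398	0.00092726867
1:Del:T:4	0.0001048869	0.2606003	0.00024897936
1:Del:T:5	0.0020163301	0.3018512	0.00074227234
1:Ins:C:0	0.00088057253	0.00017507041	0.00016773469
1:Ins:C:1	0.051081871	0.0002403486	0.0074711335
1:Ins:C:2	0.05211003	0.0018553656	0.0017102186
1:Ins:C:3	0.009908839	0.0013655614	0.002656998
1:Ins:C:4	0.0029484322	0.0017248173	0.0019169083
1:Ins:C:5	0.0030303029	0.0026200946	0.00031605937
1:Ins:T:0	0.0005339744	0.00051553969	0.0043303492
1:Ins:T:1	0.0074925887	0.0034076797	0.002483539
1:Ins:T:2	0.0031756354	0.00319588	0.00029139164
1:Ins:T:3	0.15052957	0.0004405161	0.00016669457
1:Ins:T:4	0.25021748	0.00049633302	0.0060402372
1:Ins:T:5	0.30033562	0.0035318991	0.0014944132
2:Del:R:0	0.0061490193	0.0036165851	0.25042433
2:Del:R:1	0.0013500669	0.00092002281	0.00026478715
2:Del:R:2	0.0033715411	0.00052509108	0.0026646857
2:Del:R:3	0.002360185	0.00040632306	0.0025789452
2:Del:R:4	0.0013031989	0.001834381	0.0050051666
2:Del:R:5	0.00036607828	0.0032049988	0.00022370418
3:Del:R:0	0.0011538185	0.00041784804	0.20105677
3:Del:R:1	0.0010803424	0.003112836	0.0051272769
3:Del:R:2	0.0015623597	0.013972923	0.0038555033
3:Del:R:3	0.0014287629	0.00053503134	0.015394775
3:Del:R:4	0.00073925379	0.00096815398	0.002508187
3:Del:R:5	0.0024548352	0.002507048	0.0014783054
4:Del:R:0	0.00053510801	0.00033476207	0.10034841
4:Del:R:1	0.010203133	0.0047110434	0.0019423167
4:Del:R:2	0.0007479062	0.00081400557	0.0025296692
4:Del:R:3	0.0013747266	0.0014655579	0.0019383385
4:Del:R:4	0.0065682565	0.0014498144	0.00062078942
4:Del:R:5	0.0022772203	0.0031462857	0.00098824836
5+:Del:R:0	0.0019453918	0.00040226733	0.0017467045
5+:Del:R:1	0.0014241418	0.0023809733	0.0012075223
5+:Del:R:2	0.0025320012	0.001141044	0.0076191416
5+:Del:R:3	0.0012951012	0.0018316626	0.00031387244
5+:Del:R:4	0.0012181554	0.00082218182	0.002481
5+:Del:R:5	0.0057210816	6.239583e-05	0.010770897
2:Ins:R:0	0.0018330196	0.00017245129	0.15168825
2:Ins:R:1	0.00062312436	0.0014099276	0.0027808745
2:Ins:R:2	0.0013817075	0.0022177808	0.0050178222
2:Ins:R:3	0.0017766129	0.0017139518	0.0014753108
2:Ins:R:4	0.0030022975	0.0025467359	1.187869e-05
2:Ins:R:5	0.0010785168	0.00037588837	0.00011812345
3:Ins:R:0	2.6234457e-05	0.001715031	0.00013620095
3:Ins:R:1	0.00055260321	0.0073065827	0.00068982862
3:Ins:R:2	0.0041673229	0.0018538971	0.0036910643
3:Ins:R:3	0.0027813845	0.00099465589	0.0020472793
3:Ins:R:4	0.0016342993	0.0077017377	0.0020142149
3:Ins:R:5	0.00018978583	0.0016945149	0.0021196612
4:Ins:R:0	0.0019999318	0.0014718182	4.7302567e-06
4:Ins:R:1	0.00344472	0.00068957828	0.00083886822
4:Ins:R:2	0.0038967	0.0014591185	0.00075172809
4:Ins:R:3	0.0063609749	0.0026501099	0.0014747745
4:Ins:R:4	0.0032122804	0.00015429013	0.001868786
4:Ins:R:5	0.00074780346	0.010196133	0.0032067495
5+:Ins:R:0	0.0066786228	0.0037277276	0.00027936828
5+:Ins:R:1	0.0045728783	0.00023175138	0.0037803193
5+:Ins:R:2	0.00012385103	0.0019560781	0.0085744709
5+:Ins:R:3	0.0053656697	0.0011784513	0.00090827903
5+:Ins:R:4	0.0013050899	0.0016884232	0.001290686
5+:Ins:R:5	0.0010713031	0.00048772685	0.00080778757
2:Del:M:1	0.00063669125	0.0024468089	0.00057308093
3:Del:M:1	0.00084433565	0.0018902411	0.0007186645
3:Del:M:2	1.7766156e-05	0.00011973194	0.00010038075
4:Del:M:1	0.0010867536	0.00094286728	0.00077184125
4:Del:M:2	0.00094430343	0.00611367	0.0034260738
4:Del:M:3	0.0020785903	0.0019136891	0.0014898463
5+:Del:M:1	0.00076216254	0.00025029571	0.0044643776
5+:Del:M:2	0.00016557672	0.0036741018	0.00080647841
5+:Del:M:3	4.4289003e-06	0.001772937	0.0059994322
5+:Del:M:4	0.00016469386	0.0099484124	0.0034193091
5+:Del:M:5	0.0027383797	0.00036589163	0.0021740791
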