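age,sex,q
30,male,0.0010499999999999999
31,male,0.0010933641699363674
32,male,0.0011409071203933355
33,male,0.0011930315388122862
34,male,0.0012501789175382455
35,male,0.0013128332932475168
36,male,0.0013815253467245967
37,male,0.0014568368977133611
38,male,0.0015394058329137883
39,male,0.0016299315088642071
40,male,0.0017291806754713337
41,male,0.0018379939703602258
42,male,0.0019572930390511132
43,male,0.0020880883412708047
44,male,0.0022314877095179039
45,male,0.0023887057323726366
46,male,0.002561074042027663
47,male,0.0027500525931749677
48,male,0.002957242028780672
49,male,0.0031843972374855458
50,male,0.0034334422174619951
51,male,0.0037064863726239956
52,male,0.0040058423792183901
53,male,0.0043340457741270766
54,male,0.0046938764307924595
55,male,0.0050883821046666233
56,male,0.0055209042476135461
57,male,0.0059951063099115617
58,male,0.0065150047695732832
59,male,0.0070850031518003972
60,male,0.0077099293267171775
61,male,0.0083950764012934616
62,male,0.0091462475518104807
63,male,0.0099698051765993168
64,male,0.010872724785374228
65,male,0.01186265408160201
66,male,0.012947977738333376
67,male,0.014137888416145763
68,male,0.015442464624717604
69,male,0.016872756087519338
70,male,0.018440877332657663
71,male,0.0201601103025849
72,male,0.022045016851774651
73,male,0.024111562085216039
74,male,0.026377249582399967
75,male,0.028861269652140743
76,male,0.031584661873947296
77,male,0.034570493302664491
78,male,0.037844053845773357
79,male,0.041433070468189656
80,male,0.0453679420388702
81,male,0.04968199680837028
82,male,0.054411774698180093
83,male,0.059597336792823252
84,male,0.065282604656105678
85,male,0.071515732345515087
86,male,0.078349514275721538
87,male,0.085841832385771352
88,male,0.094056146397469079
89,male,0.10306203131741994
90,male,0.11293576673536217
91,male,0.12376098291012755
92,male,0.13562936911556048
93,male,0.14864145024606651
94,male,0.16290743825961476
95,male,0.17854816566989565
96,male,0.195696108994283
97,male,0.21449651082617668
98,male,0.23510861003564884
99,male,0.25770699051815377
100,male,0.28248305991516987
101,male,0.30964667083149161
102,male,0.33942789828083703
103,male,0.37207898841468723
104,male,0.40787649504003032
105,male,0.44712362202226136
106,male,0.4901527914133188
107,male,0.53732845905703053
108,male,0.58905020151977261
109,male,0.64575610049264609
110,male,1
30,female,0.00054999999999999992
31,female,0.00057518976599849471
32,female,0.00060291762924122511
33,female,0.00063343932603084616
34,female,0.00066703636042049735
35,female,0.0007040186005482234
36,female,0.00074472713657561967
37,female,0.00078953742658970138
38,female,0.00083886275948290095
39,female,0.00089315806674961063
40,female,0.00095292411835577935
41,female,0.0010187121413804017
42,female,0.0010911289040269993
43,female,0.0011708423118953421
44,female,0.0012585875681282693
45,female,0.0013551739542491379
46,female,0.0014614922942301069
47,female,0.0015785231706329519
48,female,0.0017073459686005421
49,female,0.0018491488311124325
50,female,0.0020052396173226876
51,female,0.0021770579650495724
52,female,0.0023661885686704102
53,female,0.0025743757948847
54,female,0.0028035397711478442
55,female,0.0030557940951604001
56,female,0.0033334653287488965
57,female,0.0036391144559318228
58,female,0.0039755605030802783
59,female,0.0043459065390238855
60,female,0.0047535682949030496
61,female,0.0052023056677307413
62,female,0.0056962573982236699
63,female,0.0062399792427392711
64,female,0.0068384859913813443
65,female,0.0074972977198106685
66,female,0.0082224907013447902
67,female,0.0090207534489132948
68,female,0.009899448403748061
69,female,0.010866679839768212
70,female,0.0119313686099473
71,female,0.013103334424054539
72,female,0.014393386416624165
73,female,0.015813422840468674
74,female,0.017376540805217115
75,female,0.019097157073005779
76,female,0.020991141025429642
77,female,0.023075961028119353
78,female,0.025370845542876004
79,female,0.027896960473313786
80,female,0.030677604379683716
81,female,0.033738423363360047
82,female,0.037107647602886602
83,female,0.040816351723173681
84,female,0.044898741399251499
85,female,0.049392468837949607
86,female,0.054338980047214984
87,female,0.059783897095961679
88,female,0.065777438890064932
89,female,0.072374884345350776
90,female,0.0796370822294626
91,female,0.087631012374916606
92,female,0.0964304034394598
93,female,0.10611641291138335
94,female,0.11677837563153473
95,female,0.12851462773570727
96,female,0.14143341361669359
97,female,0.15565388427098673
98,female,0.17130719623796029
99,female,0.18853772126713186
100,female,0.20750437787036738
101,female,0.22838209704004034
102,female,0.25136343565157876
103,female,0.27666035243094439
104,female,0.30450616286693249
105,female,0.33515769109860455
106,female,0.36889763862488489
107,female,0.40603719168311925
108,female,0.44691889134465596
109,female,0.49191979279857212
110,female,1
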