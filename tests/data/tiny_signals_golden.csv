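drug,pt,soc,a,b,c,d,ror,ror_low,ror_high,prr,chi2,ic,ic025,passed,exclusion_reason
leuprolide,Fall,"Injury, poisoning and procedural complications",2,9,0,27,14.473684210526315,0.6361400021017669,329.31042527416133,11.666666666666668,5.181818181818182,1.212303603712864,-1.380764077625207,False,below_min_n
leuprolide,Urinary tract toxicity,Renal and urinary disorders,2,9,1,26,5.777777777777778,0.46613773104865175,71.61556301027795,4.909090909090909,2.25307038640372,0.8694158901898557,-1.7236517911482154,False,below_min_n
leuprolide,Abdominal pain,Gastrointestinal disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Amenorrhoea,Reproductive system and breast disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Anxiety,Psychiatric disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Asthenia,General disorders and administration site conditions,1,10,1,26,2.6,0.14798595955245766,45.68000924171277,2.4545454545454546,0.4549195660306771,0.4753380095466579,-3.3077628154184726,False,below_min_n
leuprolide,Breast cancer recurrent,"Neoplasms benign, malignant and unspecified (including cysts and polyps)",1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Embolic stroke,Nervous system disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Fatigue,General disorders and administration site conditions,1,10,1,26,2.6,0.14798595955245766,45.68000924171277,2.4545454545454546,0.4549195660306771,0.4753380095466579,-3.3077628154184726,False,below_min_n
leuprolide,Mood altered,Psychiatric disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Noninfective oophoritis,Reproductive system and breast disorders,1,10,1,26,2.6,0.14798595955245766,45.68000924171277,2.4545454545454546,0.4549195660306771,0.4753380095466579,-3.3077628154184726,False,below_min_n
leuprolide,Osteonecrosis,Musculoskeletal and connective tissue disorders,1,10,4,23,0.575,0.05686711464202363,5.813992886420774,0.6136363636363636,0.22409958167533925,-0.37656335146420805,-4.159664176429338,False,below_min_n
leuprolide,Overdose,"Injury, poisoning and procedural complications",1,10,3,24,0.8,0.07401322098457892,8.64710374019998,0.8181818181818182,0.0338680926916221,-0.1443899093351748,-3.927490734300305,False,below_min_n
leuprolide,Pelvic pain,Reproductive system and breast disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Pollakiuria,Renal and urinary disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Suicidal ideation,Psychiatric disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Vaginal haemorrhage,Reproductive system and breast disorders,1,10,0,27,7.857142857142857,0.2960550888850446,208.52434629665157,7.0,2.520884520884521,0.925999418556223,-2.8571014064089075,False,below_min_n
leuprolide,Vomiting,Gastrointestinal disorders,1,10,1,26,2.6,0.14798595955245766,45.68000924171277,2.4545454545454546,0.4549195660306771,0.4753380095466579,-3.3077628154184726,False,below_min_n
goserelin,Deep vein thrombosis,Vascular disorders,1,3,1,33,11.0,0.540436935625774,223.8929133514786,8.5,3.4926470588235294,1.078002512001273,-2.7050983129638575,False,below_min_n
goserelin,Depression,Psychiatric disorders,1,3,2,32,5.333333333333333,0.36701615111406166,77.50188747307868,4.25,1.7988795518207283,0.8786937037778666,-2.9044071211872637,False,below_min_n
goserelin,Malignant neoplasm progression,"Neoplasms benign, malignant and unspecified (including cysts and polyps)",1,3,0,34,29.571428571428573,1.0026139984926403,872.1894857540442,21.0,8.72972972972973,1.3093280581077287,-2.473772766857402,False,below_min_n
goserelin,Malignant spinal cord compression,"Neoplasms benign, malignant and unspecified (including cysts and polyps)",1,3,2,32,5.333333333333333,0.36701615111406166,77.50188747307868,4.25,1.7988795518207283,0.8786937037778666,-2.9044071211872637,False,below_min_n
goserelin,Osteonecrosis,Musculoskeletal and connective tissue disorders,1,3,4,30,2.5,0.20684856120878223,30.215341907510656,2.125,0.5486631016042781,0.5474877953024935,-3.235613029662637,False,below_min_n
goserelin,Overdose,"Injury, poisoning and procedural complications",1,3,3,31,3.4444444444444446,0.26769434726141267,44.319940455367195,2.833333333333333,0.9943771626297578,0.7036069972197752,-3.079493827745355,False,below_min_n
goserelin,Renal impairment,Renal and urinary disorders,1,3,0,34,29.571428571428573,1.0026139984926403,872.1894857540442,21.0,8.72972972972973,1.3093280581077287,-2.473772766857402,False,below_min_n
goserelin,Weight increased,Investigations,1,3,0,34,29.571428571428573,1.0026139984926403,872.1894857540442,21.0,8.72972972972973,1.3093280581077287,-2.473772766857402,False,below_min_n
triptorelin,Delayed menarche,Reproductive system and breast disorders,1,0,0,37,225.0,3.2220388861912945,15712.100874065727,57.0,38.0,1.5109619192773793,-2.2721389056877515,False,below_min_n
triptorelin,Malignant spinal cord compression,"Neoplasms benign, malignant and unspecified (including cysts and polyps)",1,0,2,35,42.6,1.3550755089883049,1339.2316427849064,11.4,11.981981981981981,1.3734583955274444,-2.409642429437686,False,below_min_n
buserelin,Hypertension,Vascular disorders,1,0,0,37,225.0,3.2220388861912945,15712.100874065727,57.0,38.0,1.5109619192773793,-2.2721389056877515,False,below_min_n
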