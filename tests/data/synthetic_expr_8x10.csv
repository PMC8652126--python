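gene,c1,c2,c3,c4,c5,c6,c7,c8,c9,c10
g1,0.0012301533574825742,0.2987455375084699,-0.2741378553622176,-0.8905918387572742,-0.45467078517172255,-0.9916465549964624,0.060143602597438485,1.3402152455545335,-0.49220651855132963,-0.6204748998199404
g2,0.4898420501851982,0.35688700816006075,0.10541424899789856,-0.9304680447082047,-0.02925182246327349,0.6953031944582878,-1.344214547285082,-0.45761576104021817,-1.901222739800844,-1.289537739784976
g3,-3.5756377540028357,-0.4564178378827784,-2.4606848418662928,0.5266463757355805,0.3043245047814144,-0.3629172108338108,-4.88616486905361,-1.0458456926094313,-0.09416219375879309,0.21998380869540743
g4,-2.9706831328197887,-0.9275344258714353,-1.8997465361285177,-1.570317613982783,2.0596823609856654,-1.567788750028478,-0.06313928640200744,1.7169993154196772,-1.1330314609594332,-0.21686382673575888
g5,0.21446068677718533,0.1238291694320664,-2.37838547555264,0.1478225025576618,2.638088665364137,-3.003705097913407,1.668449109873508,0.23171995515957614,-1.2453831371938269,3.8837100777591775
g6,-1.7840401160465358,-1.9943184099950246,-1.5538379450529802,-0.7692969426007715,1.5766598983512494,-0.6609086614006323,-0.12063670849399336,2.1389612597654795,0.4673527679766375,-0.8615455310648745
g7,3.2679709709634683,-0.07209228692460502,2.2364268471112245,-1.6386057070520659,-0.8401511720295997,0.11487592219591257,5.086905188432073,2.0416611725479297,-1.2428173406910035,-0.9831999162973986
g8,0.46307997676440565,-2.098559072259122,1.5754462569498964,-0.22399192786237054,-1.0042038787395835,3.264008270210818,-1.7573126572566329,-0.5671929985224529,0.8172758599339268,-1.8053649519088495
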