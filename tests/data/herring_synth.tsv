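year	1	2	3	4	5	6	7	8	9
1986	106.80943415950887	NA	NA	NA	NA	NA	NA	NA	NA
1987	104.49391214485284	141.290031787519	NA	NA	NA	NA	NA	NA	NA
1988	107.95690060261455	145.12879594972566	176.4654023916129	NA	NA	NA	NA	NA	NA
1989	106.93088812872816	143.2701481780275	176.5200838708579	230.5562794327824	NA	NA	NA	NA	NA
1990	105.97210508469026	144.19546522319197	174.59477527290946	228.8072113951224	262.37053462269233	NA	NA	NA	NA
1991	106.63737719345802	141.68968704607494	175.82614200601574	227.3132909111921	268.52708741393604	289.98646448627534	NA	NA	NA
1992	105.25925469141441	145.1128575558964	173.31553756861751	232.9584452017409	268.71768767734807	293.5258421845041	311.2692572563346	NA	NA
1993	107.37244466271856	142.09224430351333	175.41169109754935	229.9763355756494	265.45977496723077	292.2817645358624	309.2949915242335	323.27701833031284	NA
1994	104.36109542799679	144.7924531595857	174.41421549754662	230.03297712614378	267.75911334240686	291.5663380418569	310.1569208056738	324.64700508316497	332.9030501454914
1995	104.8761481178667	144.36432148810752	176.55119447039985	231.66503262246877	266.40776313897777	293.6771320366104	309.3860309935043	323.20523641402355	331.018887258842
1996	107.53077021794557	142.64389230686987	175.24935147214111	227.9776998555031	264.5409427686135	293.16906229738	309.68255703542263	325.14146236015097	334.0012708316067
1997	NA	143.17302903098116	174.20102421200332	230.05612070813552	265.34790141467084	294.527380209183	312.2761529016771	324.3738261611334	335.1945970459418
1998	NA	NA	174.11790337591168	226.28347070882188	265.4180997073269	294.3067752625143	307.6478369067684	320.99519187528864	333.17002407878147
1999	NA	NA	NA	228.5157135781872	267.2465499615712	292.90790288215345	310.63096780023676	323.23973345502844	332.2973100277854
2000	NA	NA	NA	NA	262.89793613208394	291.65201881959456	312.2647572379347	321.35813086832417	333.26215859071
2001	NA	NA	NA	NA	NA	289.6965985551538	311.0385646874554	323.2908104355595	330.67007803249305
2002	NA	NA	NA	NA	NA	NA	308.3681772252912	324.8709968328118	333.85020293561485
2003	NA	NA	NA	NA	NA	NA	NA	321.915009859797	333.82971481255987
2004	NA	NA	NA	NA	NA	NA	NA	NA	333.73620091394685
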