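county,use_kg_2017,use_kg_2023,pct_change_use,acres_2017,acres_2023,pct_change_acres
Adams,6281.8,28350.7,351.3,138000,139000,0.7
Alexander,1565.9,12709.8,711.7,34400,62315,81.1
Bond,3837.4,15990.6,316.7,84300,78400,-7.0
Boone,2098.5,9953.3,374.3,46100,48800,5.9
Brown,1670.6,6812.3,307.8,36700,33400,-9.0
Bureau,7146.7,33755.7,372.3,157000,165500,5.4
Calhoun,978.7,3977.3,306.4,21500,19500,-9.3
Carroll,2144.0,9667.8,350.9,47100,47400,0.6
Cass,2995.2,12196.9,307.2,65800,59800,-9.1
Champaign,11744.2,53234.0,353.3,258000,261000,1.2
Christian,8330.2,34367.5,312.6,183000,168500,-7.9
Clark,4711.3,19172.4,306.9,103500,94000,-9.2
Clay,5075.5,20396.2,301.9,111500,100000,-10.3
Clinton,5052.7,21212.0,319.8,111000,104000,-6.3
Coles,5348.6,23353.6,336.6,117500,114500,-2.6
Cook,265.8,1860.6,600.0,5839,9122,56.2
Crawford,4165.1,18132.2,335.3,91500,88900,-2.8
Cumberland,3391.3,13665.4,303.0,74500,67000,-10.1
Dekalb,5712.8,24883.3,335.6,125500,122000,-2.8
Dewitt,4520.2,32354.0,615.8,99300,158628,59.7
Douglas,5189.3,22129.8,326.5,114000,108500,-4.8
Dupage,91.6,540.1,489.8,2012,2648,31.6
Edgar,7624.6,31920.0,318.6,167500,156500,-6.6
Edwards,2175.9,10238.9,370.6,47800,50200,5.0
Effingham,4643.1,19233.6,314.2,102000,94300,-7.5
Fayette,6896.3,28452.7,312.6,151500,139500,-7.9
Ford,6054.2,27126.9,348.1,133000,133000,0.0
Franklin,3846.5,15929.4,314.1,84500,78100,-7.6
Fulton,5462.4,25495.2,366.7,120000,125000,4.2
Gallatin,3892.0,21840.9,461.2,85500,107084,25.2
Greene,4533.8,21619.9,376.9,99600,106000,6.4
Grundy,4369.9,17907.8,309.8,96000,87800,-8.5
Hamilton,4597.5,24750.3,438.3,101000,121348,20.1
Hancock,7169.4,32531.9,353.8,157500,159500,1.3
Hardin,235.6,1775.4,653.4,5177,8705,68.2
Henderson,2767.6,12135.7,338.5,60800,59500,-2.1
Henry,8057.1,35183.4,336.7,177000,172500,-2.5
Iroquois,13200.8,58944.9,346.5,290000,289000,-0.3
Jackson,4410.9,21228.3,381.3,96900,104080,7.4
Jasper,5348.6,22537.8,321.4,117500,110500,-6.0
Jefferson,4574.8,20253.4,342.7,100500,99300,-1.2
Jersey,2540.0,10667.2,320.0,55800,52300,-6.3
Jo Daviess,2148.6,9647.4,349.0,47200,47300,0.2
Johnson,1028.8,5746.8,458.6,22600,28176,24.7
Kane,2699.3,11197.5,314.8,59300,54900,-7.4
Kankakee,6372.8,28146.7,341.7,140000,138000,-1.4
Kendall,2936.1,12013.3,309.2,64500,58900,-8.7
Knox,5940.4,26515.0,346.4,130500,130000,-0.4
Lake,482.3,3418.0,608.7,10595,7600,-28.3
Lasalle,11493.8,52930.6,360.5,252500,259500,2.8
Lawrence,3823.7,16357.7,327.8,84000,80200,-4.5
Lee,5803.8,27534.8,374.4,127500,135000,5.9
Livingston,13064.3,57721.1,341.8,287000,283000,-1.4
Logan,7123.9,31206.1,338.0,156500,153000,-2.2
Macon,6281.8,45080.4,617.6,138000,221024,60.2
Macoupin,7419.8,34571.5,365.9,163000,169500,4.0
Madison,5462.4,22843.7,318.2,120000,112000,-6.7
Marion,4756.9,19478.3,309.5,104500,95500,-8.6
Marshall,3687.1,16500.5,347.5,81000,80900,-0.1
Mason,4374.5,18254.6,317.3,96100,89500,-6.9
Massac,1646.5,7261.0,341.0,36171,35600,-1.6
McDonough,5530.7,26107.1,372.0,121500,128000,5.3
Mchenry,2958.8,19510.9,559.4,65000,95660,47.2
Mclean,14179.5,61596.4,334.4,311500,302000,-3.0
Menard,3036.2,13094.3,331.3,66700,64200,-3.7
Mercer,4916.2,21721.9,341.8,108000,106500,-1.4
Monroe,3860.1,17030.8,341.2,84800,83500,-1.5
Montgomery,7123.9,32124.0,350.9,156500,157500,0.6
Morgan,5667.3,24271.4,328.3,124500,119000,-4.4
Moultrie,3709.9,16602.5,347.5,81500,81400,-0.1
Ogle,5007.2,23149.6,362.3,110000,113500,3.2
Peoria,3973.9,17459.1,339.3,87300,85600,-1.9
Perry,4278.9,17805.9,316.1,94000,87300,-7.1
Piatt,6008.7,24169.5,302.2,132000,118500,-10.2
Pike,5963.1,26515.0,344.6,131000,130000,-0.8
Pope,714.7,4496.4,529.2,15700,22045,40.4
Pulaski,2007.4,8811.1,338.9,44100,43200,-2.0
Putnam,1229.0,5323.4,333.1,27000,26100,-3.3
Randolph,5212.1,23251.6,346.1,114500,114000,-0.4
Richland,4165.1,16949.2,306.9,91500,83100,-9.2
Rock Island,2071.2,10177.7,391.4,45500,49900,9.7
Saline,2599.2,11299.5,334.7,57100,55400,-3.0
Sangamon,7670.1,35081.4,357.4,168500,172000,2.1
Schuyler,2890.5,11952.2,313.5,63500,58600,-7.7
Scott,2207.7,10646.8,382.3,48500,52200,7.6
Shelby,8079.8,36203.2,348.1,177500,177500,0.0
St. Clair,5143.8,22129.8,330.2,113000,108500,-4.0
Stark,3259.2,13502.3,314.3,71600,66200,-7.5
Stephenson,4074.1,16418.9,303.0,89500,80500,-10.1
Tazewell,5462.4,24679.4,351.8,120000,121000,0.8
Union,1606.9,6791.9,322.7,35300,33300,-5.7
Vermilion,9786.8,42831.9,337.6,215000,210000,-2.3
Wabash,2289.7,10667.2,365.9,50300,52300,4.0
Warren,5485.2,42096.6,667.5,120500,206395,71.3
Washington,6759.7,30900.2,357.1,148500,151500,2.0
Wayne,7101.1,32633.9,359.6,156000,160000,2.6
White,5849.3,24781.3,323.7,128500,121500,-5.4
Whiteside,4433.7,20375.8,359.6,97400,99900,2.6
Will,5121.0,20804.1,306.2,112500,102000,-9.3
Williamson,1543.1,7301.8,373.2,33900,35800,5.6
Winnebago,2494.5,10973.1,339.9,54800,53800,-1.8
Woodford,5599.0,23761.5,324.4,123000,116500,-5.3
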