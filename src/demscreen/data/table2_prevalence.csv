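region,year,prevalence_thousands
World,2010,40121
World,2015,46780
World,2020,54266
World,2025,63454
World,2030,74689
World,2035,87880
World,2040,102151
World,2045,116778
World,2050,131454
High-income countries,2010,17028
High-income countries,2015,19502
High-income countries,2020,21965
High-income countries,2025,24733
High-income countries,2030,27951
High-income countries,2035,31716
High-income countries,2040,35706
High-income countries,2045,39143
High-income countries,2050,42177
Other,2010,23093
Other,2015,27278
Other,2020,32301
Other,2025,38721
Other,2030,46738
Other,2035,56164
Other,2040,66445
Other,2045,77636
Other,2050,89278
China,2010,8146
China,2015,9518
China,2020,11118
China,2025,13322
China,2030,16184
China,2035,19358
China,2040,22290
China,2045,25132
China,2050,27856
Canada,2010,483
Canada,2015,556
Canada,2020,639
Canada,2025,748
Canada,2030,886
Canada,2035,1056
Canada,2040,1221
Canada,2045,1349
Canada,2050,1452
USA,2010,3760
USA,2015,4227
USA,2020,4778
USA,2025,5468
USA,2030,6397
USA,2035,7513
USA,2040,8661
USA,2045,9597
USA,2050,10285
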