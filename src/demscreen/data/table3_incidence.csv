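region,year,age_range,incidence_thousands
World,2010,60-79,5470
World,2020,60-79,7247
World,2030,60-79,10083
World,2010,60+,10124
World,2020,60+,13927
World,2030,60+,19195
High-income countries,2010,60-79,1622
High-income countries,2020,60-79,2014
High-income countries,2030,60-79,2440
High-income countries,2010,60+,4046
High-income countries,2020,60+,5302
High-income countries,2030,60+,6813
Other,2010,60-79,4010
Other,2020,60-79,5523
Other,2030,60-79,7981
Other,2010,60+,5726
Other,2020,60+,8082
Other,2030,60+,11523
China,2010,60-79,1195
China,2020,60-79,1709
China,2030,60-79,2542
China,2010,60+,1636
China,2020,60+,2365
China,2030,60+,3512
Canada,2010,60-79,43
Canada,2020,60-79,62
Canada,2030,60-79,81
Canada,2010,60+,95
Canada,2020,60+,131
Canada,2030,60+,183
USA,2010,60-79,363
USA,2020,60-79,510
USA,2030,60-79,645
USA,2010,60+,813
USA,2020,60+,1045
USA,2030,60+,1412
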