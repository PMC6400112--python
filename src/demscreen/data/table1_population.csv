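region,year,age_range,population_thousands
World,2010,all,6958169
World,2030,all,8551199
World,2010,60+,769413
World,2030,60+,1406105
World,2010,80+,106575
World,2030,80+,201868
High-income countries,2010,all,1148592
High-income countries,2030,all,1249896
High-income countries,2010,60+,241336
High-income countries,2030,60+,359030
High-income countries,2010,80+,47618
High-income countries,2030,80+,83047
Other,2010,all,5809577
Other,2030,all,7301302
Other,2010,60+,528077
Other,2030,60+,1047075
Other,2010,80+,58958
Other,2030,80+,118821
China,2010,all,1359755
China,2030,all,1441182
China,2010,60+,171120
China,2030,60+,361620
China,2010,80+,18777
China,2030,80+,40843
Canada,2010,all,34169
Canada,2030,all,40618
Canada,2010,60+,6819
Canada,2030,60+,11849
Canada,2010,80+,1345
Canada,2030,80+,2606
USA,2010,all,308641
USA,2030,all,354712
USA,2010,60+,56707
USA,2030,60+,91720
USA,2010,80+,11170
USA,2030,80+,19274
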