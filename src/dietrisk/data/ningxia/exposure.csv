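category,di_g_per_day,ef_day_per_year,ed_years,bw_kg,lt_years
drinking_water,1546.39,365,70,54.93,70
meat,42.41,304.09,70,54.93,70
cereal,313.92,365,70,54.93,70
beans,23.75,64.35,70,54.93,70
potatoes,17.24,128.17,70,54.93,70
solanaceous_fruit,111.28,235.31,70,54.93,70
vegetables,152.69,316.46,70,54.93,70
fruit,240.59,220.86,70,54.93,70
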