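category,quantity,mean,sd
drinking_water,hi,0.95,2.01
meat,hi,1.14,1.12
cereal,hi,1.69,2.38
beans,hi,0.47,0.48
potatoes,hi,0.25,0.24
solanaceous_fruit,hi,1.39,1.96
vegetables,hi,1.39,1.58
fruit,hi,1.35,9.06
drinking_water,r,0.000358,0.000891
meat,r,0.000331,0.000396
cereal,r,0.000152,0.000752
potatoes,r,3.9e-05,6.4e-05
solanaceous_fruit,r,0.000256,0.000709
vegetables,r,2.7e-05,0.000183
fruit,r,0.000324,0.00405
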