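year,quarter,cases
2013,1,1439
2013,2,2437
2013,3,2976
2013,4,1175
2014,1,3350
2014,2,1990
2014,3,3422
2014,4,3062
2015,1,2552
2015,2,2151
2015,3,4381
2015,4,3699
2016,1,3387
2016,2,3336
2016,3,3228
2016,4,3890
2017,1,3180
2017,2,3554
2017,3,3706
2017,4,4020
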