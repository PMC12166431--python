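Cell_line,Concentration,logConc,Repeat_1,Repeat_2,Repeat_3
MDAMB468,5.00E-08,-7.30103,100,100,100
MDAMB468,3E-07,-6.52288,70.57607,66.23268,53.81605
MDAMB468,6E-07,-6.22185,61.12453,42.88114,51.27202
MDAMB468,1.2E-06,-5.92082,50.81063,41.32718,45.79256
MDAMB468,2.4E-06,-5.61979,47.70611,35.1533,48.53229
MDAMB468,4.8E-06,-5.31876,39.66885,31.12138,43.05284
MDAMB468,9.6E-06,-5.01773,29.32046,21.79756,31.89824
MDAMB468,1.92E-05,-4.7167,20.38634,15.58169,14.48141
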