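ingredient,n_before,n_after,printed_relative_decrease_pct,dispensing_volume
hydrocodone,905,855,5.52,4570914825
oxycodone,762,708,7.09,3373604063
tramadol,485,434,10.52,2403511798
codeine,742,687,7.41,1986127916
morphine,320,264,17.50,467226515
hydromorphone,157,114,27.39,184212536
tapentadol,83,53,36.14,48107328
fentanyl,187,137,26.74,36317430
oxymorphone,150,111,26.00,34595913
dihydrocodeine,78,47,39.74,1889020
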