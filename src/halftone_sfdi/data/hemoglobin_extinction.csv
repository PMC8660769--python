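wavelength_nm,chromophore,epsilon
470,HbO2,0.0076467009
470,HHb,0.0037201486
500,HbO2,0.004803653
500,HHb,0.0046132753
625,HbO2,0.0001842068
625,HHb,0.0013267495
650,HbO2,8.47351e-05
650,HHb,0.000863497
685,HbO2,6.49329e-05
685,HHb,0.0005082818
700,HbO2,6.6775e-05
700,HHb,0.0004131482
750,HbO2,0.0001192739
750,HHb,0.0003235685
800,HbO2,0.0001878909
800,HHb,0.0001753925
850,HbO2,0.0002436135
850,HHb,0.0001591823
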