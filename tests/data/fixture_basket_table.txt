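                     M1 lbs      M1 USD      M3 lbs      M3 USD      M5 lbs      M5 USD
vegetables             4.63        6.30        4.63        6.30        4.63        6.30
fruits                 3.09        4.20        3.09        4.20        3.09        4.20
grains                 3.71        3.37        3.70        3.36        3.70        3.36
dairy                  3.86        4.41        3.86        4.41        3.86        4.41
protein foods          1.55        2.93        1.54        2.80        1.54        5.60
miscellaneous          0.00        0.00        0.00        0.00        0.00        0.00
Total                 16.84       21.21       16.82       21.07       16.82       23.87
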