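                      M1 lbs      M1 USD      M3 lbs      M3 USD      M5 lbs      M5 USD
beef                    1.55        2.93        0.00        0.00        1.54        5.60
pork                    0.00        0.00        1.54        2.80        0.00        0.00
cured meat              0.00        0.00        0.00        0.00        0.00        0.00
poultry                 0.00        0.00        0.00        0.00        0.00        0.00
eggs                    0.00        0.00        0.00        0.00        0.00        0.00
seafood                 0.00        0.00        0.00        0.00        0.00        0.00
nuts-seeds-soy          0.00        0.00        0.00        0.00        0.00        0.00
Total                   1.55        2.93        1.54        2.80        1.54        5.60
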