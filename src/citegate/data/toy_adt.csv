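barcode,adt
TOY001,4.4475
TOY002,3.7262
TOY003,3.9169
TOY004,4.0584
TOY005,3.5564
TOY006,4.2134
TOY007,4.4608
TOY008,3.7836
TOY009,4.8876
TOY010,3.8692
TOY011,3.9087
TOY012,3.8928
TOY013,3.6813
TOY014,4.188
TOY015,4.009
TOY016,4.7476
TOY017,1.7913
TOY018,1.2305
TOY019,0.9608
TOY020,0.6155
TOY021,0.8465
TOY022,0.5289
TOY023,1.0497
TOY024,1.1169
TOY025,0.0784
TOY026,1.0095
TOY027,1.2934
TOY028,1.0762
TOY029,0.5716
TOY030,1.5721
TOY031,0.6878
TOY032,0.4484
TOY033,0.5148
TOY034,0.9946
TOY035,1.4434
TOY036,1.5256
TOY037,1.0954
TOY038,0.4639
TOY039,0.7054
TOY040,0.5969
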