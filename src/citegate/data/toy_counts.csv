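barcode,CD3D,CD3E,HNRNPLL,RPS1,RPL1,T01,T02,T03,T04,T05,T06,T07,T08,T09,T10,T11,T12,T13
TOY001,3,2,5,10,7,0,8,2,2,5,5,2,6,2,1,3,6,1
TOY002,2,3,2,7,11,3,7,1,4,2,4,7,4,4,5,1,3,4
TOY003,4,0,6,5,4,3,12,3,0,3,2,5,4,2,7,0,4,3
TOY004,1,3,3,6,3,4,8,3,5,3,3,7,2,5,0,5,3,6
TOY005,0,1,4,5,9,1,7,4,3,4,1,4,3,2,5,5,4,3
TOY006,3,5,5,5,8,3,13,2,6,5,5,6,5,2,2,4,5,2
TOY007,2,4,4,8,10,1,11,2,5,4,2,2,1,1,1,1,2,3
TOY008,2,3,6,11,8,1,10,6,2,3,3,2,0,2,3,5,5,4
TOY009,3,1,2,8,8,3,9,4,2,5,4,2,3,3,3,3,3,2
TOY010,1,1,4,6,7,1,7,3,3,6,2,3,3,2,2,2,6,6
TOY011,4,2,3,7,7,3,11,3,2,2,3,2,4,0,0,1,2,0
TOY012,2,1,4,3,6,2,12,1,5,2,4,0,5,1,3,5,1,2
TOY013,2,2,5,4,6,1,12,3,5,4,2,3,2,7,4,2,3,0
TOY014,1,1,4,11,5,1,6,2,4,4,2,5,4,5,4,2,1,2
TOY015,4,1,5,7,10,5,14,3,1,3,4,3,5,6,2,5,3,1
TOY016,2,1,5,10,8,3,10,2,7,1,2,4,1,1,3,2,1,3
TOY017,4,2,6,8,12,21,5,3,5,4,4,4,4,5,4,0,2,1
TOY018,2,1,4,9,13,18,1,4,3,2,6,5,3,2,6,1,2,5
TOY019,1,1,4,7,8,19,1,2,4,4,2,1,6,3,4,1,4,0
TOY020,3,1,4,8,9,9,1,2,1,2,3,3,7,3,3,7,1,2
TOY021,1,1,5,7,8,15,7,2,1,0,3,2,2,2,4,2,4,2
TOY022,2,0,2,8,6,9,4,3,0,2,3,4,2,4,2,2,2,2
TOY023,2,4,2,9,8,21,2,1,6,6,4,3,3,1,2,4,3,2
TOY024,3,1,6,11,8,12,5,5,3,4,3,6,2,2,4,4,4,5
TOY025,1,5,6,7,12,11,4,4,3,6,2,1,7,5,3,1,2,4
TOY026,2,0,6,7,11,7,2,0,3,3,4,3,2,2,3,2,3,4
TOY027,1,0,4,10,5,14,5,1,4,4,3,1,4,4,2,3,3,6
TOY028,6,2,3,8,15,17,2,2,1,2,2,4,3,3,5,2,1,2
TOY029,4,6,7,5,8,14,2,2,1,1,3,1,5,5,4,1,3,5
TOY030,1,1,2,11,3,14,8,2,2,2,4,3,4,0,5,7,4,0
TOY031,3,2,6,12,6,15,2,5,3,4,8,4,2,3,3,5,3,5
TOY032,1,1,6,5,14,15,3,2,4,4,2,1,7,3,3,4,5,3
TOY033,5,4,4,4,11,11,4,4,0,3,2,4,1,2,3,2,4,3
TOY034,0,2,5,7,10,7,3,2,5,2,3,4,9,2,6,3,2,3
TOY035,0,1,3,5,14,10,4,5,1,2,0,7,3,3,2,5,5,2
TOY036,0,4,3,15,6,11,1,2,3,2,3,2,1,4,2,4,4,2
TOY037,4,1,1,13,6,18,3,0,3,0,3,4,3,3,3,2,2,2
TOY038,3,1,3,6,15,6,2,4,3,3,3,1,3,5,6,2,4,4
TOY039,0,3,5,9,10,7,5,2,2,2,2,4,2,3,3,0,1,2
TOY040,0,4,3,8,12,9,2,1,1,2,2,5,6,3,5,1,5,5
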