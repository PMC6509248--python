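trial,CAUS3,HEBE3,LAPO3,NDHY1,NORM3,OTT,PINT2,PRIN2,STAU2,STRO1,STS1
HEBE3_06,,1.000,-0.330,,0.870,,,0.359,0.670,0.310,-0.034
LAPO3_06,,-0.330,1.000,,-0.499,,,-0.068,-0.008,0.363,0.435
NORM3_06,,0.870,-0.499,,1.000,,,0.281,0.584,0.157,-0.200
PRIN2_06,,0.359,-0.068,,0.281,,,1.000,0.236,0.205,0.223
STAU2_06,,0.670,-0.008,,0.584,,,0.236,1.000,0.526,0.151
STRO1_06,,0.310,0.363,,0.157,,,0.205,0.526,1.000,0.235
STS1_06,,-0.034,0.435,,-0.200,,,0.223,0.151,0.235,1.000
HEBE3_07,,1.000,0.302,,0.829,,0.519,,0.677,-0.084,-0.008
LAPO3_07,,0.302,1.000,,0.431,,0.132,,0.054,0.339,0.452
NORM3_07,,0.829,0.431,,1.000,,0.479,,0.701,-0.078,0.038
PINT2_07,,0.519,0.132,,0.479,,1.000,,0.597,0.300,0.001
STAU2_07,,0.677,0.054,,0.701,,0.597,,1.000,-0.156,-0.184
STRO1_07,,-0.084,0.339,,-0.078,,0.300,,-0.156,1.000,0.705
STS1_07,,-0.008,0.452,,0.038,,0.001,,-0.184,0.705,1.000
HEBE3_08,,1.000,,,0.419,-0.093,0.429,0.348,0.476,0.517,0.001
NORM3_08,,0.419,,,1.000,-0.002,0.425,0.432,0.466,-0.081,-0.336
OTT_08,,-0.093,,,-0.002,1.000,-0.298,-0.397,-0.284,0.027,0.183
PINT2_08,,0.429,,,0.425,-0.298,1.000,0.620,0.402,0.388,-0.200
PRIN2_08,,0.348,,,0.432,-0.397,0.620,1.000,0.543,0.186,-0.260
STAU2_08,,0.476,,,0.466,-0.284,0.402,0.543,1.000,0.206,-0.242
STRO1_08,,0.517,,,-0.081,0.027,0.388,0.186,0.206,1.000,0.476
STS1_08,,0.001,,,-0.336,0.183,-0.200,-0.260,-0.242,0.476,1.000
CAUS3_09,1.000,,-0.438,-0.387,0.486,-0.283,0.712,0.299,,-0.251,
LAPO3_09,-0.438,,1.000,0.321,-0.225,0.583,-0.411,-0.024,,0.591,
NDHY1_09,-0.387,,0.321,1.000,-0.267,0.573,-0.216,0.044,,0.231,
NORM3_09,0.486,,-0.225,-0.267,1.000,-0.218,0.445,0.094,,-0.070,
OTT_09,-0.283,,0.583,0.573,-0.218,1.000,-0.184,0.153,,0.589,
PINT2_09,0.712,,-0.411,-0.216,0.445,-0.184,1.000,0.148,,-0.250,
PRIN2_09,0.299,,-0.024,0.044,0.094,0.153,0.148,1.000,,0.190,
STRO1_09,-0.251,,0.591,0.231,-0.070,0.589,-0.250,0.190,,1.000,
CAUS3_10,1.000,0.521,-0.277,0.178,0.474,0.017,,0.127,0.397,0.008,
HEBE3_10,0.521,1.000,-0.053,0.387,0.630,0.231,,0.234,0.492,0.140,
LAPO3_10,-0.277,-0.053,1.000,-0.029,-0.021,-0.276,,-0.025,-0.303,-0.008,
NDHY1_10,0.178,0.387,-0.029,1.000,0.316,0.050,,0.080,0.296,0.498,
NORM3_10,0.474,0.630,-0.021,0.316,1.000,,,0.409,0.588,0.200,
OTT_10,0.017,0.231,-0.276,0.050,,1.000,,0.093,0.206,0.062,
PRIN2_10,0.127,0.234,-0.025,0.080,0.409,0.093,,1.000,0.196,0.085,
STAU2_10,0.397,0.492,-0.303,0.296,0.588,0.206,,0.196,1.000,0.383,
STRO1_10,0.008,0.140,-0.008,0.498,0.200,0.062,,0.085,0.383,1.000,
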