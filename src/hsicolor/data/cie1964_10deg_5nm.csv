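wavelength_nm,xbar,ybar,zbar
380,0.000160,0.000017,0.000705
385,0.000774,0.000083,0.003429
390,0.002362,0.000253,0.010482
395,0.007887,0.000833,0.035292
400,0.019110,0.002004,0.086011
405,0.044660,0.004627,0.202919
410,0.084736,0.008756,0.389366
415,0.140866,0.014349,0.658085
420,0.204492,0.021391,0.972542
425,0.263319,0.029373,1.275352
430,0.314679,0.038676,1.553480
435,0.359819,0.049708,1.814345
440,0.383734,0.062077,1.967280
445,0.379955,0.074910,1.987491
450,0.370702,0.089456,1.994800
455,0.344172,0.107073,1.909476
460,0.302273,0.128201,1.745370
465,0.252365,0.154690,1.552013
470,0.195618,0.185190,1.317560
475,0.134540,0.217659,1.038834
480,0.080507,0.253589,0.772125
485,0.040613,0.293307,0.571465
490,0.016172,0.339133,0.415254
495,0.007403,0.395924,0.302441
500,0.003816,0.460777,0.218502
505,0.014713,0.531552,0.156661
510,0.037465,0.606741,0.112044
515,0.071560,0.686666,0.082477
520,0.117749,0.761757,0.060709
525,0.173018,0.822569,0.043519
530,0.236491,0.875211,0.030451
535,0.304410,0.925350,0.020901
540,0.376772,0.961988,0.013676
545,0.451164,0.981242,0.008003
550,0.529826,0.991761,0.003988
555,0.616157,0.995725,0.001288
560,0.705224,0.997340,0.000000
565,0.794723,0.983493,0.000000
570,0.878655,0.955552,0.000000
575,0.950686,0.916322,0.000000
580,1.014160,0.868934,0.000000
585,1.079779,0.824981,0.000000
590,1.118520,0.777405,0.000000
595,1.122554,0.720494,0.000000
600,1.123990,0.658341,0.000000
605,1.092446,0.593862,0.000000
610,1.030480,0.527963,0.000000
615,0.951920,0.461962,0.000000
620,0.856297,0.398057,0.000000
625,0.754678,0.339161,0.000000
630,0.647467,0.283493,0.000000
635,0.536218,0.228694,0.000000
640,0.431567,0.179828,0.000000
645,0.343642,0.140240,0.000000
650,0.268329,0.107633,0.000000
655,0.204548,0.081254,0.000000
660,0.152568,0.060281,0.000000
665,0.112331,0.044145,0.000000
670,0.081261,0.031800,0.000000
675,0.058053,0.022650,0.000000
680,0.040851,0.015905,0.000000
685,0.028683,0.011154,0.000000
690,0.019941,0.007749,0.000000
695,0.013873,0.005388,0.000000
700,0.009577,0.003718,0.000000
705,0.006632,0.002571,0.000000
710,0.004553,0.001768,0.000000
715,0.003105,0.001230,0.000000
720,0.002089,0.000846,0.000000
725,0.001395,0.000558,0.000000
730,0.000925,0.000360,0.000000
735,0.000635,0.000246,0.000000
740,0.000437,0.000169,0.000000
745,0.000297,0.000115,0.000000
750,0.000200,0.000077,0.000000
755,0.000135,0.000052,0.000000
760,0.000091,0.000035,0.000000
765,0.000062,0.000024,0.000000
770,0.000042,0.000016,0.000000
775,0.000028,0.000010,0.000000
780,0.000019,0.000007,0.000000
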