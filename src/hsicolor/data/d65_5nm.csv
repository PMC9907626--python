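wavelength_nm,power
380,49.980
385,52.315
390,54.650
395,68.700
400,82.750
405,87.120
410,91.490
415,92.460
420,93.430
425,90.055
430,86.680
435,95.770
440,104.860
445,110.935
450,117.010
455,117.410
460,117.810
465,116.335
470,114.860
475,115.390
480,115.920
485,112.365
490,108.810
495,109.080
500,109.350
505,108.575
510,107.800
515,106.295
520,104.790
525,106.240
530,107.690
535,106.050
540,104.410
545,104.230
550,104.050
555,102.025
560,100.000
565,98.165
570,96.330
575,96.060
580,95.790
585,92.240
590,88.690
595,89.350
600,90.010
605,89.805
610,89.600
615,88.650
620,87.700
625,85.495
630,83.290
635,83.495
640,83.700
645,81.865
650,80.030
655,80.120
660,80.210
665,81.245
670,82.280
675,80.280
680,78.280
685,74.000
690,69.720
695,70.665
700,71.610
705,72.980
710,74.350
715,67.975
720,61.600
725,65.745
730,69.890
735,72.490
740,75.090
745,69.340
750,63.590
755,55.005
760,46.420
765,56.615
770,66.810
775,65.095
780,63.380
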