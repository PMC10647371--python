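wavelength_nm,R,G,B
400.0,0.0,8.4e-05,0.135335
410.0,0.0,0.000335,0.249352
420.0,0.0,0.001204,0.411112
430.0,0.0,0.003866,0.606531
440.0,1e-06,0.011109,0.800737
450.0,4e-06,0.028566,0.945959
460.0,1.9e-05,0.065729,1.0
470.0,8.4e-05,0.135335,0.945959
480.0,0.000335,0.249352,0.800737
490.0,0.001204,0.411112,0.606531
500.0,0.003866,0.606531,0.411112
510.0,0.011109,0.800737,0.249352
520.0,0.028566,0.945959,0.135335
530.0,0.065729,1.0,0.065729
540.0,0.135335,0.945959,0.028566
550.0,0.249352,0.800737,0.011109
560.0,0.411112,0.606531,0.003866
570.0,0.606531,0.411112,0.001204
580.0,0.800737,0.249352,0.000335
590.0,0.945959,0.135335,8.4e-05
600.0,1.0,0.065729,1.9e-05
610.0,0.945959,0.028566,4e-06
620.0,0.800737,0.011109,1e-06
630.0,0.606531,0.003866,0.0
640.0,0.411112,0.001204,0.0
650.0,0.249352,0.000335,0.0
660.0,0.135335,8.4e-05,0.0
670.0,0.065729,1.9e-05,0.0
680.0,0.028566,4e-06,0.0
690.0,0.011109,1e-06,0.0
700.0,0.003866,0.0,0.0
710.0,0.001204,0.0,0.0
720.0,0.000335,0.0,0.0
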