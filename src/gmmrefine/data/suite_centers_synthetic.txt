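# Synthetic RNA backbone suite-center table (46 clusters).
# Constructed stand-in following the suitename convention: columns are the
# 7 suite dihedrals (delta-1, epsilon-1, zeta-1, alpha, beta, gamma, delta).
# The first data row gives per-dimension half-widths (degrees) for the
# scaled distance metric; remaining rows are 'name' + 7 center angles.
widths 28 60 55 50 70 35 28
1a 81 -148 -71 -65 174 54 81
1m 81 -148 -150 -65 -140 -64 81
1L 81 -98 -71 165 135 -64 81
&a 147 -148 -150 165 135 54 147
7a 147 -98 -71 -65 174 -64 81
3a 81 -148 80 65 135 -64 81
9a 147 -148 80 -65 135 178 81
1g 147 -98 80 -65 -140 178 147
7d 147 -98 -150 165 174 178 147
3d 81 -148 -150 65 -140 54 147
5d 81 -148 -150 165 174 -64 81
1e 81 -148 -71 -65 135 178 147
1c 81 -148 -71 165 -140 -64 81
1f 147 -148 -71 165 174 178 81
5j 147 -98 -150 65 -140 -64 81
5n 81 -98 -150 65 -140 178 147
5p 81 -98 -71 -65 135 54 147
1b 147 -148 -150 65 174 54 147
1[ 81 -98 80 -65 135 178 81
3b 147 -98 -71 165 -140 178 147
1z 147 -98 -150 165 174 54 147
5z 81 -148 80 -65 -140 54 147
7p 81 -98 -150 -65 135 54 81
5q 81 -98 80 -65 -140 -64 147
1t 81 -148 -150 -65 135 178 81
5r 147 -148 -71 -65 -140 -64 147
2a 81 -98 -150 65 174 178 147
4a 81 -98 80 65 174 -64 147
0a 147 -98 -71 65 135 178 147
0g 81 -98 -150 165 -140 -64 81
4g 147 -148 -71 165 -140 -64 81
6g 147 -98 80 65 -140 178 81
8d 147 -98 -71 -65 135 -64 147
4d 147 -148 -150 65 135 54 81
6d 147 -148 -71 65 174 -64 81
2h 147 -148 -71 165 -140 178 147
4n 147 -148 -150 165 135 54 81
0i 147 -98 80 165 135 54 147
6n 81 -148 80 -65 174 -64 81
6j 147 -148 -71 -65 -140 54 147
2[ 81 -98 80 165 174 -64 147
4b 81 -148 -71 -65 -140 178 147
0b 81 -98 -150 -65 -140 -64 81
4p 147 -98 80 65 -140 54 81
6p 81 -148 -71 165 174 178 147
2z 147 -98 80 65 174 178 81
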