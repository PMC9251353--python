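subject,condition,va_od,va_os,randot,yans,distance_randot,gfdrdss
1,habitual,0.05,0.05,20,40,100,60
2,habitual,0.05,0.05,20,40,60,60
3,habitual,-0.1,0,20,40,60,60
4,habitual,0.15,0.1,25,40,100,100
5,habitual,0.15,0.05,50,40,60,60
6,habitual,0,0,20,40,100,100
7,uncorrected,0.1,0,20,40,400,200
7,corrected,0,0,20,40,60,60
8,habitual,-0.1,-0.1,20,40,60,40
9,habitual,0,-0.1,25,40,60,40
10,habitual,0,0.1,20,40,60,40
11,habitual,0.1,-0.1,30,40,60,60
12,habitual,0.1,0.1,200,200,60,40
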