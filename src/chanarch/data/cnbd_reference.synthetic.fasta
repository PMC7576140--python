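>reference synthetic C-linker+CNBD element template
QGAATWPSNWTAVASEVNGLADRQQKCCRQRKDSMHLVWINHPIKVFQDTTFVAIELTFA
KEDPGREWKDQWLYLLQCYLSLMTKSRWDSWYAVCYEYVTLFTWGNLWASQASASLWAVA
ILYNGFVFDGPNTNGKTQYKNPVEKWATKTAKAQGRWDVAKLLYTGGVVLICHEVTR
>elements per-column element codes (a-f=A'-F', 1-8=beta strands, A/B=helices, P=PBC)
--aaaaaaaaaaa---bbbbbbbbbbbb--cccccccccc---ddddddddd--eeeeee
eeee---fffffffff----111111--222222--333333--44444--AAAAAAAAA
A--PPPPPPPP--555555--666666--777777--888888--BBBBBBBBBB--
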