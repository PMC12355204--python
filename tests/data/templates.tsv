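# hand-written retro transformations: SMARTS<TAB>id<TAB>prior
[C:1](=[O:2])[O:3][C:4]>>[C:1](=[O:2])[OH].[OH:3]-[C:4]	retro-ester	0.9
[C:1](=[O:2])[NX3;H1:3]>>[C:1](=[O:2])[OH].[NH2:3]	retro-amide	0.9
[C;!$(C=O):1][O:2][C;!$(C=O):3]>>[C:1][OH:2].[C:3]Br	retro-ether	0.8
[C:1][NH:2][CH2:3]>>[C:1][NH2:2].[CH1:3]=O	retro-amine	0.8
[C:1][C:2]([OH:3])>>[C:1]Br.[C:2]=[O:3]	retro-grignard	0.7
[CH2:1][CH2:2]>>[CH1:1]=[CH1:2]	retro-hydrogenation	0.6
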