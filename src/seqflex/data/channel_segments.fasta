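>TRPV3_mouse_S6pi S6 pi-region consensus window, mouse TRPV3 offset=662
ILTFVLLLNML
>TRPV6_human_S6pi S6 pi-region window, human TRPV6 offset=563
IIATLLMLNLL
>TRPM4_human_S6pi S6 pi-region window, human TRPM4 offset=1028
LVANILLVNLL
>TRPM8_mouse_S6pi S6 pi-region window, mouse TRPM8 offset=964
LSTNILLVNLL
>TRPC3_human_S6pi S6 pi-region window, human TRPC3 offset=728
VTMVVVLLNML
>TRPA1_human_S6pi S6 pi-region window, human TRPA1 offset=945
IFVPIVLMNLL
>TRPV1_rat_S4 S4 segment A546-G558, rat TRPV1; reconstructed transcription offset=545
AMGWTNMLYYTRG
>hERG_human_S5PH S5-PH linker M574-L586, human hERG; transcription of the S5-P linker offset=573
MEQPHMDSRIGWL
>TRPA1_human_PH2 PH2 pi-region N917-E924, human TRPA1; SYNTHETIC partial reconstruction, unknown interior residues as X offset=916
NDRXSXXE
>TRPV3_human_S45L S4-S5 linker central region G573-I579, human TRPV3; SYNTHETIC partial reconstruction, unknown interior residues as X offset=572
GXXXXXI
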