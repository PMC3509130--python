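>A1 source=metagenome genus=Faecalibacterium annotations=COG0001,K00001
MAGWTEKLVNDESTARFGQYLMKESATVWDNK
>A2 source=metagenome genus=Faecalibacterium annotations=COG0001,K00001
MAGWTEKLVNDESTARFGQYLIKESGTVWDNK
>B1 source=metagenome genus=Bacteroides annotations=COG0002,K00002
MPQWYHNCFDEKGGVTLSDNRAEQILPMYKTTSGWVADFR
>B2 source=metagenome genus=Bacteroides annotations=COG0002,K00002
MPQWYHNCFDEKGGVTISDNRAEQILPMYKTTSGWVAEFR
>X1 source=metagenome
MAGWTEKWDYHQATNLECFGSVRPPLDNAAGYTSIK
>HUMAN01 source=human
MSSTELFKAQWDNPLRGVYEQIKDDSTAVLR
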