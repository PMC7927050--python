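category	description
1:Del:C:0	1 bp C deletion, homopolymer length 0
1:Del:C:1	1 bp C deletion, homopolymer length 1
1:Del:C:2	1 bp C deletion, homopolymer length 2
1:Del:C:3	1 bp C deletion, homopolymer length 3
1:Del:C:4	1 bp C deletion, homopolymer length 4
1:Del:C:5	1 bp C deletion, homopolymer length >=6
1:Del:T:0	1 bp T deletion, homopolymer length 0
1:Del:T:1	1 bp T deletion, homopolymer length 1
1:Del:T:2	1 bp T deletion, homopolymer length 2
1:Del:T:3	1 bp T deletion, homopolymer length 3
1:Del:T:4	1 bp T deletion, homopolymer length 4
1:Del:T:5	1 bp T deletion, homopolymer length >=6
1:Ins:C:0	1 bp C insertion, existing run length 0
1:Ins:C:1	1 bp C insertion, existing run length 1
1:Ins:C:2	1 bp C insertion, existing run length 2
1:Ins:C:3	1 bp C insertion, existing run length 3
1:Ins:C:4	1 bp C insertion, existing run length 4
1:Ins:C:5	1 bp C insertion, existing run length >=5
1:Ins:T:0	1 bp T insertion, existing run length 0
1:Ins:T:1	1 bp T insertion, existing run length 1
1:Ins:T:2	1 bp T insertion, existing run length 2
1:Ins:T:3	1 bp T insertion, existing run length 3
1:Ins:T:4	1 bp T insertion, existing run length 4
1:Ins:T:5	1 bp T insertion, existing run length >=5
2:Del:R:0	2 bp deletion, 0 extra tandem copies
2:Del:R:1	2 bp deletion, 1 extra tandem copies
2:Del:R:2	2 bp deletion, 2 extra tandem copies
2:Del:R:3	2 bp deletion, 3 extra tandem copies
2:Del:R:4	2 bp deletion, 4 extra tandem copies
2:Del:R:5	2 bp deletion, 5 extra tandem copies
3:Del:R:0	3 bp deletion, 0 extra tandem copies
3:Del:R:1	3 bp deletion, 1 extra tandem copies
3:Del:R:2	3 bp deletion, 2 extra tandem copies
3:Del:R:3	3 bp deletion, 3 extra tandem copies
3:Del:R:4	3 bp deletion, 4 extra tandem copies
3:Del:R:5	3 bp deletion, 5 extra tandem copies
4:Del:R:0	4 bp deletion, 0 extra tandem copies
4:Del:R:1	4 bp deletion, 1 extra tandem copies
4:Del:R:2	4 bp deletion, 2 extra tandem copies
4:Del:R:3	4 bp deletion, 3 extra tandem copies
4:Del:R:4	4 bp deletion, 4 extra tandem copies
4:Del:R:5	4 bp deletion, 5 extra tandem copies
5+:Del:R:0	5+ bp deletion, 0 extra tandem copies
5+:Del:R:1	5+ bp deletion, 1 extra tandem copies
5+:Del:R:2	5+ bp deletion, 2 extra tandem copies
5+:Del:R:3	5+ bp deletion, 3 extra tandem copies
5+:Del:R:4	5+ bp deletion, 4 extra tandem copies
5+:Del:R:5	5+ bp deletion, 5 extra tandem copies
2:Ins:R:0	2 bp insertion, 0 existing tandem copies
2:Ins:R:1	2 bp insertion, 1 existing tandem copies
2:Ins:R:2	2 bp insertion, 2 existing tandem copies
2:Ins:R:3	2 bp insertion, 3 existing tandem copies
2:Ins:R:4	2 bp insertion, 4 existing tandem copies
2:Ins:R:5	2 bp insertion, 5 existing tandem copies
3:Ins:R:0	3 bp insertion, 0 existing tandem copies
3:Ins:R:1	3 bp insertion, 1 existing tandem copies
3:Ins:R:2	3 bp insertion, 2 existing tandem copies
3:Ins:R:3	3 bp insertion, 3 existing tandem copies
3:Ins:R:4	3 bp insertion, 4 existing tandem copies
3:Ins:R:5	3 bp insertion, 5 existing tandem copies
4:Ins:R:0	4 bp insertion, 0 existing tandem copies
4:Ins:R:1	4 bp insertion, 1 existing tandem copies
4:Ins:R:2	4 bp insertion, 2 existing tandem copies
4:Ins:R:3	4 bp insertion, 3 existing tandem copies
4:Ins:R:4	4 bp insertion, 4 existing tandem copies
4:Ins:R:5	4 bp insertion, 5 existing tandem copies
5+:Ins:R:0	5+ bp insertion, 0 existing tandem copies
5+:Ins:R:1	5+ bp insertion, 1 existing tandem copies
5+:Ins:R:2	5+ bp insertion, 2 existing tandem copies
5+:Ins:R:3	5+ bp insertion, 3 existing tandem copies
5+:Ins:R:4	5+ bp insertion, 4 existing tandem copies
5+:Ins:R:5	5+ bp insertion, 5 existing tandem copies
2:Del:M:1	2 bp deletion with 1 bp flanking microhomology
3:Del:M:1	3 bp deletion with 1 bp flanking microhomology
3:Del:M:2	3 bp deletion with 2 bp flanking microhomology
4:Del:M:1	4 bp deletion with 1 bp flanking microhomology
4:Del:M:2	4 bp deletion with 2 bp flanking microhomology
4:Del:M:3	4 bp deletion with 3 bp flanking microhomology
5+:Del:M:1	5+ bp deletion with 1 bp flanking microhomology
5+:Del:M:2	5+ bp deletion with 2 bp flanking microhomology
5+:Del:M:3	5+ bp deletion with 3 bp flanking microhomology
5+:Del:M:4	5+ bp deletion with 4 bp flanking microhomology
5+:Del:M:5	5+ bp deletion with 5 bp flanking microhomology
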