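# Study collection grid: 42 avenanthramides (39 grid members + 3 standards).
# Reconstruction: codes follow the published AVN shorthand; per-code substitution
# patterns are rebuilt from that convention, not copied from a machine-readable source.
code,name,scaffold,A3,A4,A5,A6,B2,B3,B4,B5,standard,smiles
1a,N-(cinnamoyl) anthranilic acid (AVN 1a),monoene,H,H,H,H,H,H,H,H,0,
1p,N-(p-coumaroyl) anthranilic acid (AVN 1p),monoene,H,H,H,H,H,H,OH,H,0,
1c,N-(caffeoyl) anthranilic acid (AVN 1c),monoene,H,H,H,H,H,OH,OH,H,0,
1f,N-(feruloyl) anthranilic acid (AVN 1f),monoene,H,H,H,H,H,OCH3,OH,H,0,
1s,N-(sinapoyl) anthranilic acid (AVN 1s),monoene,H,H,H,H,H,OCH3,OH,OCH3,0,
2a,N-(cinnamoyl) 5-hydroxyanthranilic acid (AVN 2a),monoene,H,H,OH,H,H,H,H,H,0,
2p,N-(p-coumaroyl) 5-hydroxyanthranilic acid (AVN 2p),monoene,H,H,OH,H,H,H,OH,H,0,
2c,N-(caffeoyl) 5-hydroxyanthranilic acid (AVN 2c),monoene,H,H,OH,H,H,OH,OH,H,0,
2f,N-(feruloyl) 5-hydroxyanthranilic acid (AVN 2f),monoene,H,H,OH,H,H,OCH3,OH,H,0,
2s,N-(sinapoyl) 5-hydroxyanthranilic acid (AVN 2s),monoene,H,H,OH,H,H,OCH3,OH,OCH3,0,
2m,N-(4-methoxycinnamoyl) 5-hydroxyanthranilic acid (AVN 2m),monoene,H,H,OH,H,H,H,OCH3,H,0,
3a,N-(cinnamoyl) 4-hydroxyanthranilic acid (AVN 3a),monoene,H,OH,H,H,H,H,H,H,0,
3p,N-(p-coumaroyl) 4-hydroxyanthranilic acid (AVN 3p),monoene,H,OH,H,H,H,H,OH,H,0,
3c,N-(caffeoyl) 4-hydroxyanthranilic acid (AVN 3c),monoene,H,OH,H,H,H,OH,OH,H,0,
3f,N-(feruloyl) 4-hydroxyanthranilic acid (AVN 3f),monoene,H,OH,H,H,H,OCH3,OH,H,0,
3h(1),N-(2-hydroxycinnamoyl) 4-hydroxyanthranilic acid (AVN 3h(1)),monoene,H,OH,H,H,OH,H,H,H,0,
3h(2),N-(3-hydroxycinnamoyl) 4-hydroxyanthranilic acid (AVN 3h(2)),monoene,H,OH,H,H,H,OH,H,H,0,
4p,N-(p-coumaroyl) 4-methoxyanthranilic acid (AVN 4p),monoene,H,OCH3,H,H,H,H,OH,H,0,
4c,N-(caffeoyl) 4-methoxyanthranilic acid (AVN 4c),monoene,H,OCH3,H,H,H,OH,OH,H,0,
4f,N-(feruloyl) 4-methoxyanthranilic acid (AVN 4f),monoene,H,OCH3,H,H,H,OCH3,OH,H,0,
5a,"N-(cinnamoyl) 4,5-dihydroxyanthranilic acid (AVN 5a)",monoene,H,OH,OH,H,H,H,H,H,0,
5p,"N-(p-coumaroyl) 4,5-dihydroxyanthranilic acid (AVN 5p)",monoene,H,OH,OH,H,H,H,OH,H,0,
5c,"N-(caffeoyl) 4,5-dihydroxyanthranilic acid (AVN 5c)",monoene,H,OH,OH,H,H,OH,OH,H,0,
5f,"N-(feruloyl) 4,5-dihydroxyanthranilic acid (AVN 5f)",monoene,H,OH,OH,H,H,OCH3,OH,H,0,
5s,"N-(sinapoyl) 4,5-dihydroxyanthranilic acid (AVN 5s)",monoene,H,OH,OH,H,H,OCH3,OH,OCH3,0,
1pd,N-(dienoyl homologue of p-coumaroyl) anthranilic acid (AVN 1pd),diene,H,H,H,H,H,H,OH,H,0,
1cd,N-(dienoyl homologue of caffeoyl) anthranilic acid (AVN 1cd),diene,H,H,H,H,H,OH,OH,H,0,
1fd,N-(dienoyl homologue of feruloyl) anthranilic acid (AVN 1fd),diene,H,H,H,H,H,OCH3,OH,H,0,
2ad,N-(dienoyl homologue of cinnamoyl) 5-hydroxyanthranilic acid (AVN 2ad),diene,H,H,OH,H,H,H,H,H,0,
2pd,N-(dienoyl homologue of p-coumaroyl) 5-hydroxyanthranilic acid (AVN 2pd),diene,H,H,OH,H,H,H,OH,H,0,
2cd,N-(dienoyl homologue of caffeoyl) 5-hydroxyanthranilic acid (AVN 2cd),diene,H,H,OH,H,H,OH,OH,H,0,
2fd,N-(dienoyl homologue of feruloyl) 5-hydroxyanthranilic acid (AVN 2fd),diene,H,H,OH,H,H,OCH3,OH,H,0,
2sd,N-(dienoyl homologue of sinapoyl) 5-hydroxyanthranilic acid (AVN 2sd),diene,H,H,OH,H,H,OCH3,OH,OCH3,0,
3pd,N-(dienoyl homologue of p-coumaroyl) 4-hydroxyanthranilic acid (AVN 3pd),diene,H,OH,H,H,H,H,OH,H,0,
3cd,N-(dienoyl homologue of caffeoyl) 4-hydroxyanthranilic acid (AVN 3cd),diene,H,OH,H,H,H,OH,OH,H,0,
3fd,N-(dienoyl homologue of feruloyl) 4-hydroxyanthranilic acid (AVN 3fd),diene,H,OH,H,H,H,OCH3,OH,H,0,
5pd,"N-(dienoyl homologue of p-coumaroyl) 4,5-dihydroxyanthranilic acid (AVN 5pd)",diene,H,OH,OH,H,H,H,OH,H,0,
5cd,"N-(dienoyl homologue of caffeoyl) 4,5-dihydroxyanthranilic acid (AVN 5cd)",diene,H,OH,OH,H,H,OH,OH,H,0,
5fd,"N-(dienoyl homologue of feruloyl) 4,5-dihydroxyanthranilic acid (AVN 5fd)",diene,H,OH,OH,H,H,OCH3,OH,H,0,
Tranilast,"2-{[(2E)-3-(3,4-dimethoxyphenyl)prop-2-enoyl]amino}benzoic acid (Tranilast)",monoene,H,H,H,H,H,OCH3,OCH3,H,1,OC(=O)c1ccccc1NC(=O)/C=C/c1ccc(OC)c(OC)c1
dihydroavenanthramide D,2-{[3-(4-hydroxyphenyl)propanoyl]amino}benzoic acid (dihydroavenanthramide D),dihydro_monoene,H,H,H,H,H,H,OH,H,1,OC(=O)c1ccccc1NC(=O)CCc1ccc(O)cc1
AVN A2,2-{[3-(4-hydroxyphenyl)propanoyl]amino}-5-hydroxybenzoic acid (AVN A2),dihydro_monoene,H,H,OH,H,H,H,OH,H,1,OC(=O)c1cc(O)ccc1NC(=O)CCc1ccc(O)cc1
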