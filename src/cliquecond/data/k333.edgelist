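# complete tripartite K(3,3,3): parts {1,2,3},{4,5,6},{7,8,9}; 27 maximal cliques
1	4
1	5
1	6
2	4
2	5
2	6
3	4
3	5
3	6
1	7
1	8
1	9
2	7
2	8
2	9
3	7
3	8
3	9
4	7
4	8
4	9
5	7
5	8
5	9
6	7
6	8
6	9
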