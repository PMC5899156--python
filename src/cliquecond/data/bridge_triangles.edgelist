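# two triangles {1,2,3} and {4,5,6} joined by the bridge edge 3-4
1	2
1	3
2	3
3	4
4	5
4	6
5	6
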