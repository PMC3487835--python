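# axis s 0 1 5 -
# axis z 0 3.5 5 A^2
# temperature 310
#! FIELDS s z free_energy
0.10000000000000001 0.34999999999999998 0
0.10000000000000001 1.0499999999999998 2
0.10000000000000001 1.75 6
0.10000000000000001 2.4499999999999997 7
0.10000000000000001 3.1499999999999999 8
0.30000000000000004 0.34999999999999998 3
0.30000000000000004 1.0499999999999998 4
0.30000000000000004 1.75 6.5
0.30000000000000004 2.4499999999999997 2.5
0.30000000000000004 3.1499999999999999 7.5
0.5 0.34999999999999998 5
0.5 1.0499999999999998 6
0.5 1.75 3
0.5 2.4499999999999997 2
0.5 3.1499999999999999 6
0.70000000000000007 0.34999999999999998 7
0.70000000000000007 1.0499999999999998 4.5
0.70000000000000007 1.75 2.7999999999999998
0.70000000000000007 2.4499999999999997 1.5
0.70000000000000007 3.1499999999999999 2.2000000000000002
0.90000000000000002 0.34999999999999998 8
0.90000000000000002 1.0499999999999998 7
0.90000000000000002 1.75 6
0.90000000000000002 2.4499999999999997 2.1000000000000001
0.90000000000000002 3.1499999999999999 0.40000000000000002
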