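# Reverse-degree edge partition of the hyaluronic acid-paclitaxel conjugate
# family, indexed by the polymerization degree s >= 1.
# Columns: reverse-degree pair (a, b) and affine edge count slope*s + intercept.
a,b,slope,intercept
2,2,1,0
2,3,7,0
3,3,19,-1
2,4,3,0
3,4,32,-1
4,4,13,1
2,5,4,0
3,5,16,0
4,5,1,1
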