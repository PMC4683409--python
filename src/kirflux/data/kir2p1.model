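# Eleven-state permeation diagram for the Kir2.1 channel.
#
# Selectivity-filter (SF) patterns are written S1-S2-S3-S4 from the
# extracellular to the intracellular end; each site holds an ion (i) or a
# water molecule (w).  Ions never occupy adjacent SF sites, at least one SF
# site holds an ion, and the lumped wide-pore K+ site (cytoplasmic pore +
# central cavity) holds zero or one ion.  Wide-pore-occupied states whose S4
# site holds an ion are excluded (the wide-pore site sits directly below S4,
# so simultaneous occupancy is electrostatically forbidden); this prunes
# three of the doubled states and leaves eleven.
#
# Directed-edge semantics
#   label   rate-constant label; "free" rates are k1..k10, "derived" rates
#           are fixed by thermodynamic cycle closure (detailed balance)
#   z       electrical distance (fraction of membrane field); "dep" for
#           derived edges (solved from the cycle charge balance)
#   kplus   bimolecular K+ dependence: in -> scales with [K+]_in,
#           out -> scales with [K+]_out, none -> unimolecular
#   ion     K+ ions moved across the extracellular reference plane
#           (positive = efflux)
#   water   water molecules moved across that plane (positive = efflux)
#   sense   binding | release | efflux | influx
#
# Physical transition classes
#   k1/k2   K+ binding/release between the intracellular bulk and the
#           wide-pore site (voltage independent, z = 0)
#   k3/k4   ion release to / re-entry from the extracellular solution at S1
#           (column shift or outer-mouth ion/water exchange), two-ion SF
#   k5/k8   transfer of the wide-pore ion into S4 of a one-ion filter (no
#           concerted exit) and its return from the resulting two-ion filter
#   k6      concerted transfer of the wide-pore ion into S4 with exit at S1
#   k7      concerted transfer of the wide-pore ion into S4, two-ion SF
#           (reverse = dependent rate k32)
#   k9/k10  single-file column shift carried by water entry/exit

[states]
# index  sf          wide_pore
1        i-w-i-w     0
2        i-w-i-w     1
3        w-i-w-i     0
4        w-w-i-w     1
5        w-i-w-w     0
6        w-i-w-w     1
7        w-w-i-w     0
8        w-w-w-i     0
9        i-w-w-i     0
10       i-w-w-w     0
11       i-w-w-w     1

[edges]
# from  to  label    z      kplus  ion  water  sense
1       2   k1       0.0    in     0    0      binding
2       1   k2       0.0    none   0    0      release
5       6   k1       0.0    in     0    0      binding
6       5   k2       0.0    none   0    0      release
10      11  k1       0.0    in     0    0      binding
11      10  k2       0.0    none   0    0      release
7       4   k1       0.0    in     0    0      binding
4       7   k2       0.0    none   0    0      release
2       3   k7       0.2    none   1    0      efflux
3       2   k32      dep    out    -1   0      influx
11      8   k6       0.2    none   1    0      efflux
8       11  k8_11    dep    out    -1   0      influx
6       9   k6       0.2    none   0    1      efflux
9       6   k9_6     dep    none   0    -1     influx
4       3   k6       0.2    none   0    1      efflux
3       4   k3_4     dep    none   0    -1     influx
11      9   k5       0.3    none   0    0      efflux
9       11  k8       -0.2   none   0    0      influx
1       5   k3       0.2    none   1    0      efflux
5       1   k4       -0.2   out    -1   0      influx
9       7   k3       0.2    none   1    0      efflux
7       9   k4       -0.2   out    -1   0      influx
1       7   k3       0.2    none   1    -1     efflux
7       1   k7_1     dep    out    -1   1      influx
3       1   k9       0.1    none   0    1      efflux
1       3   k10      -0.1   none   0    -1     influx
5       10  k9       0.1    none   0    1      efflux
10      5   k10      -0.1   none   0    -1     influx
8       7   k9       0.1    none   0    1      efflux
7       8   k10      -0.1   none   0    -1     influx
4       6   k9       0.1    none   0    1      efflux
6       4   k6_4     dep    none   0    -1     influx
6       11  k9       0.1    none   0    1      efflux
11      6   k11_6    dep    none   0    -1     influx

[cycles]
# Named cyclic paths (letter, state sequence in the efflux orientation).
a   1,2,3
b   7,4,3,1
c   4,6,11,9,7
d   7,4,6,11,8
e   1,5,10,11,8,7

[checksum]
states                  11
directed_rates          34
undirected_transitions  17
simple_cycles           59
conducting_cycles       39
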