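# cc-pVDZ correlation-consistent polarized valence double-zeta basis.
# Reference data transcribed from the published compilations
# (T.H. Dunning Jr., J. Chem. Phys. 90, 1007 (1989) for H, O;
#  D.E. Woon and T.H. Dunning Jr., J. Chem. Phys. 98, 1358 (1993) for S),
# as distributed by the EMSL Basis Set Exchange (CC-BY 4.0).
# Format: "element L" header, then "exponent coefficient" lines.
# Spherical (pure) harmonics are used for d and higher shells.

H S
     13.0100000      0.0196850
      1.9620000      0.1379770
      0.4446000      0.4781480
      0.1220000      0.5012400
H S
      0.1220000      1.0000000
H P
      0.7270000      1.0000000

O S
  11720.0000000      0.0007100
   1759.0000000      0.0054700
    400.8000000      0.0278370
    113.7000000      0.1048000
     37.0300000      0.2830620
     13.2700000      0.4487190
      5.0250000      0.2709520
      1.0130000      0.0154580
O S
  11720.0000000     -0.0001600
   1759.0000000     -0.0012630
    400.8000000     -0.0062670
    113.7000000     -0.0257160
     37.0300000     -0.0709240
     13.2700000     -0.1654110
      5.0250000     -0.1169550
      1.0130000      0.5573680
O S
      0.3023000      1.0000000
O P
     17.7000000      0.0430180
      3.8540000      0.2289130
      1.0460000      0.5087280
O P
      0.2753000      1.0000000
O D
      1.1850000      1.0000000

S S
 110800.0000000      0.0002476
  16610.0000000      0.0019203
   3781.0000000      0.0099619
   1071.0000000      0.0402975
    349.8000000      0.1286040
    126.3000000      0.3034800
     49.2600000      0.4214320
     20.1600000      0.2307810
      5.7200000      0.0178971
      2.1820000     -0.0029751
S S
 110800.0000000     -0.0000662
  16610.0000000     -0.0005184
   3781.0000000     -0.0026765
   1071.0000000     -0.0107356
    349.8000000     -0.0365173
    126.3000000     -0.0945105
     49.2600000     -0.1746290
     20.1600000     -0.1371700
      5.7200000      0.4528940
      2.1820000      0.6508340
S S
      0.4327000      1.0000000
S S
      0.1570000      1.0000000
S P
    399.7000000      0.0044754
     94.1900000      0.0341708
     29.7500000      0.1442500
     10.7700000      0.3539280
      4.1190000      0.4590850
      1.6250000      0.2063830
S P
      0.4726000      1.0000000
S P
      0.1407000      1.0000000
S D
      0.4790000      1.0000000

# Fe: only the contraction pattern of the published cc-pVDZ set
# (N.B. Balabanov, K.A. Peterson, J. Chem. Phys. 123, 064107 (2005))
# is recorded: [6s5p3d1f] -> 43 spherical functions. The exponent table
# is not bundled; Fe supports dimension counting only.
Fe PATTERN 6S 5P 3D 1F
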