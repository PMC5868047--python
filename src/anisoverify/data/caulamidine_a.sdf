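
     RDKit          3D

 51 56  0  0  0  0  0  0  0  0999 V2000
   -2.1934   -2.0221   -0.5715 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2365   -0.6550   -0.3722 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0646    0.1787   -0.9384 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6656    1.4656   -0.5568 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2398    2.6508   -0.9778 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6768    3.8539   -0.5431 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5486    3.8462    0.2914 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9695    2.6472    0.7137 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5505    1.4615    0.2887 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2035    0.0177    0.5684 C   0  0  1  0  0  0  0  0  0  0  0  0
   -1.5153   -0.4077    2.0236 C   0  0  1  0  0  0  0  0  0  0  0  0
   -0.4748    0.1526    2.9849 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8992   -0.0579    2.5312 N   0  0  0  0  0  0  0  0  0  0  0  0
    1.2686   -0.1279    1.1898 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5278    0.0075    0.8708 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.9625   -0.1328   -0.4507 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.3267   -0.3065   -0.6934 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.8061   -0.4465   -1.9980 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9145   -0.4036   -3.0669 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5509   -0.2241   -2.8415 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0755   -0.0999   -1.5296 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6257    0.1428   -1.2363 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2065   -0.4737    0.1254 C   0  0  2  0  0  0  0  0  0  0  0  0
    0.2073   -2.0391    0.0450 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8841   -2.6173   -0.8522 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2927   -2.6304   -1.3218 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9195    0.2898    3.5246 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8626    5.3408    0.8014 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -3.1523    0.0639    2.6196 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    4.4997   -0.5684   -4.6761 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -4.1025    2.6389   -1.6351 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1147    4.7959   -0.8632 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0869    2.6558    1.3445 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5146   -1.4989    2.1076 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6075   -0.3329    3.9608 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294    1.2246    3.1545 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.0182   -0.3311    0.1449 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.8703   -0.5815   -2.1692 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8626   -0.1749   -3.6813 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0052   -0.2456   -2.0513 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5077    1.2319   -1.2382 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0969   -2.4665    1.0499 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1770   -2.4152   -0.3043 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6275   -2.4550   -1.9059 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9287   -3.7021   -0.6986 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2430   -2.3520   -2.3799 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2519   -3.7223   -1.2470 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2595   -2.3132   -0.9162 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.5463    0.1517    4.5452 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.2196    1.3367    3.4102 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.8024   -0.3500    3.4203 H   0  0  0  0  0  0  0  0  0  0  0  0
  7 28  1  0
 11 29  1  0
 19 30  1  0
  1  2  1  0
  1 25  1  0
  1 26  1  0
  2  3  2  0
  2 10  1  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9  4  1  0
 10  9  1  1
 10 11  1  0
 10 23  1  0
 11 12  1  0
 12 13  1  0
 13 14  1  0
 13 27  1  0
 14 15  2  0
 14 23  1  0
 15 16  1  0
 16 17  2  0
 17 18  1  0
 18 19  2  0
 19 20  1  0
 20 21  2  0
 21 16  1  0
 21 22  1  0
 23 22  1  6
 23 24  1  0
 24 25  1  0
  5 31  1  0
  6 32  1  0
  8 33  1  0
 11 34  1  6
 12 35  1  0
 12 36  1  0
 17 37  1  0
 18 38  1  0
 20 39  1  0
 22 40  1  0
 22 41  1  0
 24 42  1  0
 24 43  1  0
 25 44  1  0
 25 45  1  0
 26 46  1  0
 26 47  1  0
 26 48  1  0
 27 49  1  0
 27 50  1  0
 27 51  1  0
M  END
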