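experiment,from,to
HMBC_NH,5,3-N
HMBC_CH,5,4
HMBC_CH,5,6
HMBC_CH,5,7
HMBC_CH,5,9
HMBC_CH,6,4
HMBC_CH,6,5
HMBC_CH,6,7
HMBC_CH,6,8
HMBC_CH,8,4
HMBC_CH,8,6
HMBC_CH,8,7
HMBC_CH,8,10
HMBC_CH,11,2
HMBC_CH,11,9
HMBC_CH,11,10
HMBC_CH,11,12
HMBC_CH,11,23
HMBC_CH,12a,11
HMBC_NH,12a,13-N
HMBC_CH,12a,14
HMBC_NH,12a,15-N
HMBC_CH,12a,27
HMBC_CH,12b,11
HMBC_NH,12b,13-N
HMBC_CH,12b,14
HMBC_NH,12b,15-N
HMBC_NH,17,15-N
HMBC_CH,17,16
HMBC_CH,17,19
HMBC_CH,17,21
HMBC_CH,18,16
HMBC_CH,18,19
HMBC_CH,20,16
HMBC_CH,20,18
HMBC_CH,20,19
HMBC_CH,20,21
HMBC_CH,20,22
HMBC_CH,22a,10
HMBC_CH,22a,14
HMBC_CH,22a,16
HMBC_CH,22a,21
HMBC_CH,22a,23
HMBC_CH,22a,24
HMBC_CH,22b,10
HMBC_NH,22b,13-N
HMBC_CH,22b,14
HMBC_CH,22b,16
HMBC_CH,22b,21
HMBC_CH,22b,23
HMBC_CH,22b,24
HMBC_CH,24a,10
HMBC_CH,24a,14
HMBC_CH,24a,22
HMBC_CH,24a,23
HMBC_CH,24a,25
HMBC_NH,24b,1-N
HMBC_CH,24b,10
HMBC_CH,24b,22
HMBC_CH,24b,23
HMBC_CH,24b,25
HMBC_CH,25a,2
HMBC_NH,25a,3-N
HMBC_CH,25a,24
HMBC_CH,25b,24
HMBC_CH,25b,26
HMBC_NH,26,1-N
HMBC_CH,26,2
HMBC_NH,26,3-N
HMBC_CH,26,25
HMBC_CH,27,12
HMBC_NH,27,13-N
HMBC_CH,27,14
HMBC_NH,27,15-N
HSQC,5,5
HSQC,6,6
HSQC,8,8
HSQC,11,11
HSQC,17,17
HSQC,18,18
HSQC,20,20
HSQC,26,26
HSQC,27,27
HSQC,12a,12
HSQC,12b,12
HSQC,22a,22
HSQC,22b,22
HSQC,24a,24
HSQC,24b,24
HSQC,25a,25
HSQC,25b,25
COSY,5,6
COSY,6,8
COSY,12a,11
COSY,12b,11
COSY,25a,24
COSY,25b,24
COSY,12a,12
COSY,22a,22
LR_HSQMBC,26,24
LR_HSQMBC,5,10
LR_HSQMBC,8,11
LR_HSQMBC,17,14
LR_HSQMBC,20,23
LR_HSQMBC,22a,25
LR_HSQMBC,11,14
LR_HSQMBC,24a,11
LR_HSQMBC,26,10
LR_HSQMBC,5,11
LR_HSQMBC,6,9
HSQMBC_TOCSY,11,27
HSQMBC_TOCSY,12a,9
HSQMBC_TOCSY,5,8
HSQMBC_TOCSY,6,4
HSQMBC_TOCSY,25b,23
ADEQUATE_1_1,5,4
ADEQUATE_1_1,8,9
ADEQUATE_1_1,11,10
ADEQUATE_1_1,17,16
ADEQUATE_1_1,20,21
ADEQUATE_1_1,22a,23
ADEQUATE_1_1,24a,23
ADEQUATE_1_1,12a,11
NOESY,8,22a
NOESY,11,24a
NOESY,22b,24b
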