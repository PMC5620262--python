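study_id,author,year,country,design,size_class,gc_type,genotyping_method,nos,case_tt,case_tc,case_cc,control_tt,control_tc,control_cc,shared_control_key
Eom 2016,Eom,2016,Korea,HB,<1000,NA,GoldenGate assay (Illumina),6,176,421,249,248,424,174,
Zhang 2016,Zhang,2016,China,HB,<1000,NA,MALDI-TOF,8,10,27,23,16,34,10,
Kim 2014,Kim,2014,Korea,HB,<1000,non-cardia,GoldenGate assay (Illumina),7,97,241,137,135,242,96,
Wu 2014,Wu,2014,China,HB,<1000,NA,Multiplex SNaPshot SNP,6,48,115,54,133,209,86,
Li 2013,Li,2013,China,HB,<1000,NA,TaqMan,7,71,167,97,102,165,67,
Dong 2015,Dong,2015,China,HB,<1000,NA,iMLDR,8,62,68,37,41,91,54,
Song 2013,Song,2013,Korea,PB,>1000,non-cardia,HRM-PCR,8,682,1654,909,477,846,377,
Qiu 2015,Qiu,2015,China,PB,>1000,cardia,TaqMan,8,209,571,344,356,565,273,
Shi 2011a,Shi,2011,China,PB,<1000,non-cardia,AGWHSA 6.0 chips,8,302,517,160,507,1154,607,
Shi 2011b,Shi,2011,China,PB,>1000,non-cardia,AGWHSA 6.0 chips,8,561,941,371,464,1034,578,
Shi 2011c,Shi,2011,China,PB,>1000,non-cardia,AGWHSA 6.0 chips,8,480,675,237,376,745,392,
Shi 2011d,Shi,2011,China,PB,<1000,NA,AGWHSA 6.0 chips,8,225,447,223,898,1616,713,shi-3227
Shi 2011e,Shi,2011,China,PB,>1000,NA,AGWHSA 6.0 chips,7,459,1221,724,898,1616,713,shi-3227
Cai 2017,Cai,2017,China,PB,<1000,NA,KASP,6,88,213,172,143,246,98,
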