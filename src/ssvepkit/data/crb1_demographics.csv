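participant_id,age,sex,va_os,va_od,phenotype,disease_duration
002,48.1,F,0.22,0.16,MD,18.1
003,16.6,F,0.48,0.32,LCA/EOSRD,16.0
004,15.6,M,0.70,0.50,MD,3.6
005,17.5,F,0.50,0.50,LCA/EOSRD,13.5
006,52.2,M,0.24,0.32,MD,12.2
007,39.1,M,0.00,0.64,MD,9.1
008,17.4,M,0.04,0.02,MD,9.4
009,29.5,M,0.16,0.32,MD,11.5
011,40.5,M,0.32,1.4,CRD,20.5
012,34.3,F,0.88,0.86,MD,9.3
013,34.0,M,0.96,0.88,CRD,28.0
014,58.9,F,1.30,1.30,MD,32.0
015,16.2,M,1.58,1.98,LCA/EOSRD,16.1
016,54.1,M,HM,PL,LCA/EOSRD,49.1
017,46.1,M,PL,HM,LCA/EOSRD,40.1
018,34.1,M,HM,HM,LCA/EOSRD,33.1
019,48.2,F,0.7,0.7,CRD,18.2
020,48.5,M,0.9,1.4,MD,24.5
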