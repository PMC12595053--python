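crop,phase,variable,entropy,weight
coffee,elnino,tmax,0.7093,0.1529
coffee,elnino,tmin,0.7453,0.1340
coffee,elnino,vpd,0.6312,0.1940
coffee,elnino,pr,0.6666,0.1754
coffee,elnino,soil,0.6714,0.1728
coffee,elnino,pdsi,0.6751,0.1709
coffee,lanina,tmax,0.7109,0.1441
coffee,lanina,tmin,0.6809,0.1591
coffee,lanina,vpd,0.6453,0.1768
coffee,lanina,pr,0.6513,0.1738
coffee,lanina,soil,0.6458,0.1765
coffee,lanina,pdsi,0.6597,0.1696
cacao,elnino,tmax,0.7535,0.1698
cacao,elnino,tmin,0.7893,0.1452
cacao,elnino,vpd,0.7334,0.1837
cacao,elnino,pr,0.7526,0.1704
cacao,elnino,soil,0.7527,0.1704
cacao,elnino,pdsi,0.7670,0.1605
cacao,lanina,tmax,0.7441,0.1516
cacao,lanina,tmin,0.7281,0.1610
cacao,lanina,vpd,0.6822,0.1882
cacao,lanina,pr,0.7146,0.1690
cacao,lanina,soil,0.7124,0.1703
cacao,lanina,pdsi,0.7301,0.1599
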