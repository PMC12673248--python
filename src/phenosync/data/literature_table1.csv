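site,period,n,reported_mean_doy,reported_synchrony80,pred_mean_latelev,pred_synch_latelev,pred_mean_colwellelev,pred_synch_colwellelev
England Chedington,1968-1972,42,131,18,144,24,127,27
Germany Baden-Wuerttemberg,1973-2019,16130,141,22,145,24,145,23
Poland Czempin,1976-1980,129,153,,144,24,145,25
Italy Tyrol,1983-1992,113,164,21,154,22,156,21
Sweden Ekenas,1986-1999,233,153,25,149,24,145,25
Norway Storfosna,1991-1994,296,142,26,155,24,141,23
Norway Joa,1992-1993,45,142,28,153,25,142,22
Italy Apennines,1997-2003,117,150,17,143,23,148,23
Spain Madrid,,,139,,140,23,137,28
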