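spelling,gender,plural_class
Bach,M,e
Dach,N,er
Fach,N,er
Kind,N,er
Rind,N,er
Wind,M,e
Wand,F,e
Hand,F,e
Land,N,er
Band,N,er
Tag,M,e
Zaun,M,e
Raum,M,e
Fisch,M,e
Tisch,M,e
Hund,M,e
Fund,M,e
Brot,N,e
Lot,N,e
Spur,F,en
Kur,F,en
Uhr,F,en
Frau,F,en
Auto,N,s
Oma,F,s
Kino,N,s
Wagen,M,zero
Lehrer,M,zero
Messer,N,zero
Fenster,N,zero
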