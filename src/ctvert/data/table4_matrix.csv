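specimen_id,taxon,age_class,locality,a,b,c,d,e,f,g,h,i,j,k,l,facet_left,facet_right,facet_position_note,provenance_identity
RGM 139671,Coelodonta antiquitatis,unknown,,T,T,T,T,T,C,T,C,T,T,T,T,,,,T1
RGM 146833,Coelodonta antiquitatis,unknown,,T,C,?,C,C,X,T,?,?,X,X,X,small,small,,C/T
RGM 171525,Coelodonta antiquitatis,unknown,,C,C,?,X,C,X,C,C,C,C,C,C,,,,C7
RGM 369367,Coelodonta antiquitatis,unknown,,C,C,C,C,C,X,C,C,C,C,C,C,,,,C7
RGM 369657,Coelodonta antiquitatis,unknown,,C,C,?,X,C,C,C,C,C,C,C,C,,,,C7
RGM 445933,Coelodonta antiquitatis,unknown,,T,C,?,C,C,X,C,?,?,C,T,X,small,large,facet size and position differ between sides,C/T
RGM 55336,Coelodonta antiquitatis,unknown,,T,T,T,T,T,X,T,?,?,T,T,T,,,,T1
RGM 93477,Coelodonta antiquitatis,unknown,,X,T,C,T,X,X,C,?,?,X,T,T,small,small,,C/T
RGM 93479,Coelodonta antiquitatis,unknown,,T,T,T,T,T,C,T,T,T,T,T,T,,,,T1
RGM 93485,Coelodonta antiquitatis,unknown,,T,?,?,T,C,T,T,?,?,T,T,T,,,,T1
RGM 93790,Coelodonta antiquitatis,unknown,,X,T,X,X,C,X,T,?,?,X,X,X,large,small,facet size and position differ between sides,C/T
RGM 94549,Coelodonta antiquitatis,unknown,,T,X,C,X,C,C,C,C,C,X,T,X,small,large,left facet lies more dorsally than right; transverse and mammillary processes asymmetrically placed,C/T
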