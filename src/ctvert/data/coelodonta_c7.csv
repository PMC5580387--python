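specimen_id,taxon,age_class,locality,a,b,c,d,e,f,g,h,i,j,k,l,facet_left,facet_right,facet_position_note,provenance_identity
RGM 123268,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, 52 45N, 2 40E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 123886,Coelodonta antiquitatis,adult,"North Sea, 30-40 miles WNW of IJmuiden",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 124895,Coelodonta antiquitatis,adult,"North Sea, 52 27N, 2 25E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 132637,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, 52 40N, 2 55E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 133133,Coelodonta antiquitatis,adult,"North Sea, South of Bruine Bank",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 138907,Coelodonta antiquitatis,unknown,"North Sea, Bruine Bank, 52 30N, 3 00E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 139898,Coelodonta antiquitatis,adult,"The Netherlands, Zuid-Willemsvaart, 's-Hertogenbosch, prov. N. Brabant",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 146833,Coelodonta antiquitatis,adult,"North Sea, 52 30N, 2 30E",T,C,?,C,C,X,T,?,?,X,X,X,small,small,,C/T
RGM 152631,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, 52 30N, 3 00E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 152709,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, 52 37N, 3 02E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 153522,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, 52 10N, 2 50E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 171473,Coelodonta antiquitatis,adult,"The Netherlands, Schaar van Colijnsplaat, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 171525,Coelodonta antiquitatis,adult,"The Netherlands, Schaar van Colijnsplaat, prov. Zeeland, 51 36N, 3 52E",C,C,?,X,C,X,C,C,C,C,C,C,,,,C7
RGM 171542,Coelodonta antiquitatis,adult,"The Netherlands, Schaar van Colijnsplaat, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 369367,Coelodonta antiquitatis,juvenile,"North Sea, South of Bruine Bank",C,C,C,C,C,X,C,C,C,C,C,C,,,,C7
RGM 369657,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, between 52 50 and 53 00N, 2 50 and 3 00E",C,C,?,X,C,C,C,C,C,C,C,C,,,,C7
RGM 388048,Coelodonta antiquitatis,adult,"North Sea, Bruine Bank, between 52 50 and 53 00N, 2 50 and 3 00E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 388049,Coelodonta antiquitatis,juvenile,"North Sea, Bruine Bank, between 52 30 and 53 00N, 2 50 and 3 00E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 400927,Coelodonta antiquitatis,juvenile,"North Sea, Bruine Bank, between 52 30 and 53 00, 2 50 and 3 00E",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 445933,Coelodonta antiquitatis,adult,"The Netherlands, Westerschelde, Ellewoutsdijk, prov. Zeeland",T,C,?,C,C,X,C,?,?,C,T,X,small,large,facet size and position differ between sides,C/T
RGM 445939,Coelodonta antiquitatis,adult,"The Netherlands, Ellewoutsdijk, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 55335,Coelodonta antiquitatis,juvenile,"The Netherlands, Westerschelde, Plaat van Baarland, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 58226,Coelodonta antiquitatis,juvenile,"The Netherlands, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 63324,Coelodonta antiquitatis,juvenile,"The Netherlands, Hollands Diep, east of Moerdijkbrug; prov. N. Brabant",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 92687,Coelodonta antiquitatis,adult,"The Netherlands, 's-Hertogenbosch, between Zuid-Willemsvaart and Aa, prov. N. Brabant",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 93342,Coelodonta antiquitatis,adult,"The Netherlands, Ellewoutsdijk, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 93408,Coelodonta antiquitatis,juvenile,"The Netherlands, Ellewoutsdijk, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 93449,Coelodonta antiquitatis,adult,"The Netherlands, Ellewoutsdijk, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 93473,Coelodonta antiquitatis,juvenile,"The Netherlands, Ellewoutsdijk, Westerschelde, prov. Zeeland",C,C,C,C,C,C,C,C,C,C,C,C,,,,C7
RGM 93477,Coelodonta antiquitatis,adult,"The Netherlands, Westerschelde, Ellewoutsdijk, prov. Zeeland",X,T,C,T,X,X,C,?,?,X,T,T,small,small,,C/T
RGM 93790,Coelodonta antiquitatis,adult,"The Netherlands, between Zuid Willemsvaart en Aa, 's-Hertogenbosch, prov. N. Brabant",X,T,X,X,C,X,T,?,?,X,X,X,large,small,facet size and position differ between sides,C/T
RGM 94549,Coelodonta antiquitatis,juvenile,"The Netherlands, Westerschelde, Ellewoutsdijk, prov. Zeeland",T,X,C,X,C,C,C,C,C,X,T,X,small,large,left facet lies more dorsally than right; transverse and mammillary processes asymmetrically placed,C/T
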