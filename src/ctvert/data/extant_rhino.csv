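specimen_id,taxon,age_class,locality,a,b,c,d,e,f,g,h,i,j,k,l,provenance_identity,collection_no,institute
Ds RGM cat a,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat a,Naturalis
Ds RGM cat b,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat b,Naturalis
Ds RGM cat g,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat g,Naturalis
Ds MNHN-ZM-AC-1887-932,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1887-932,MNHN
Ds ZMUC CN3791,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN3791,ZMUC
Ds AMNH 54763,Dicerorhinus sumatrensis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 54763,AMNH
Ds AMNH 54764,Dicerorhinus sumatrensis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 54764,AMNH
Ds AMNH 81892,Dicerorhinus sumatrensis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 81892,AMNH
Cs NRM 592359,Ceratotherium simum,unknown,,C,C,C,C,C,C,C,C,C,C,C,C,C7,NRM 592359,NRM
Cs NMW 3086,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,NMW 3086,NHMW
Cs MNHN-ZM-AC-A7968,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-A7968,MNHN
Cs ZMUC CN2662,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN2662,ZMUC
Cs FMNH 29174,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,FMNH 29174,FMNH
Cs FMNH 125413,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,FMNH 125413,FMNH
Cs AMNH 51855,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51855,AMNH
Cs AMNH 51856,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51856,AMNH
Cs AMNH 51857,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51857,AMNH
Cs AMNH 51858,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51858,AMNH
Cs AMNH 51859,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51859,AMNH
Cs AMNH 51860,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51860,AMNH
Cs AMNH 51861,Ceratotherium simum,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51861,AMNH
Cs AMNH 51862,Ceratotherium simum,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 51862,AMNH
Ru MNHN-ZM-AC-1960-59,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1960-59,MNHN
Ru MNHN 1792,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN 1792,MNHN
Ru MNHN-ZM-AC-1967-101,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1967-101,MNHN
Ru AMNH 35759,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 35759,AMNH
Ru AMNH 54454,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 54454,AMNH
Ru AMNH 54456,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 54456,AMNH
Ru AMNH 119475,Rhinoceros unicornis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 119475,AMNH
Ru FMNH 57639,Rhinoceros unicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,FMNH 57639,FMNH
Rs RGM cat a,Rhinoceros sondaicus,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat a,Naturalis
Rs RGM cat c,Rhinoceros sondaicus,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat c,Naturalis
Rs RGM ZMA 507,Rhinoceros sondaicus,unknown,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM ZMA 507,Naturalis
Rs MNHN-ZM-AC-A7970,Rhinoceros sondaicus,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-A7970,MNHN
Rs MNHN-ZM-AC-A7971,Rhinoceros sondaicus,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-A7971,MNHN
Rs ZMUC CN 26,Rhinoceros sondaicus,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN 26,ZMUC
Db RGM cat a,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM cat a,Naturalis
Db RGM ZMA 506,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM ZMA 506,Naturalis
Db RGM 5738,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,RGM 5738,Naturalis
Db MNHN-ZM-AC-1941-208,Diceros bicornis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1941-208,MNHN
Db MNHN-ZM-AC-1944-278,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1944-278,MNHN
Db MNHN-ZM-AC-1936-644,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-1936-644,MNHN
Db MNHN-ZM-AC-A7969,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,MNHN-ZM-AC-A7969,MNHN
Db ZMUC CN36..,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN36..,ZMUC
Db ZMUC CN 3653,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN 3653,ZMUC
Db ZMUC CN 4435,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,ZMUC CN 4435,ZMUC
Db AMNH 14136,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 14136,AMNH
Db AMNH 27757,Diceros bicornis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 27757,AMNH
Db AMNH 34739,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 34739,AMNH
Db AMNH 35319,Diceros bicornis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 35319,AMNH
Db AMNH 81805,Diceros bicornis,juvenile,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 81805,AMNH
Db AMNH 113776,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 113776,AMNH
Db AMNH 113777,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 113777,AMNH
Db AMNH 245690,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,AMNH 245690,AMNH
Db FMNH 57809,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,FMNH 57809,FMNH
Db FMNH 127848,Diceros bicornis,adult,,C,C,C,C,C,C,C,C,C,C,C,C,C7,FMNH 127848,FMNH
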