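# Default exclusion list: domesticated species and their wild ancestors.
# Representative set assembled from common domestication knowledge;
# override with your own list via exclude_domesticated(..., exclusion_list=...).
Bos taurus
Bos indicus
Bos frontalis
Bos grunniens
Bos javanicus
Bos primigenius
Bubalus bubalis
Ovis aries
Ovis orientalis
Capra hircus
Capra aegagrus
Sus scrofa
Camelus dromedarius
Camelus bactrianus
Lama glama
Vicugna pacos
Equus caballus
Equus ferus
Equus asinus
Equus africanus
Canis familiaris
Canis lupus
Felis catus
Felis silvestris
Cavia porcellus
Oryctolagus cuniculus
Mustela putorius
Rangifer tarandus
Mesocricetus auratus
Chinchilla lanigera
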