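analyte,route,kind,value_ng_per_bee,qualifier,source,note
clothianidin,contact,hb_geomean,35.88,,US-EPA ecotoxicity database and literature geometric mean,
imidacloprid,contact,hb_geomean,40.03,,US-EPA ecotoxicity database and literature geometric mean,
imidacloprid,oral,hb_geomean,3.9,,US-EPA ecotoxicity database and literature geometric mean,
thiamethoxam,contact,hb_geomean,25.64,,US-EPA ecotoxicity database and literature geometric mean,
chlorantraniliprole,contact,hb_geomean,81500,>,US-EPA ecotoxicity database,unbounded endpoint reported as a greater-than limit
chlorantraniliprole,oral,hb_geomean,117800,>,US-EPA ecotoxicity database,unbounded endpoint reported as a greater-than limit
carbaryl,contact,hb_geomean,11200,,US-EPA ecotoxicity database,
dimethoate,oral,hb_geomean,56,,US-EPA ecotoxicity database,
methomyl,oral,hb_geomean,1.18,,US-EPA ecotoxicity database,
pyraclostrobin,contact,hb_geomean,100000,,US-EPA ecotoxicity database,
picoxystrobin,contact,hb_geomean,200000,,US-EPA ecotoxicity database,
boscalid,contact,hb_geomean,200000,,US-EPA ecotoxicity database,
boscalid,oral,hb_geomean,166000,,US-EPA ecotoxicity database,
propamocarb,contact,hb_geomean,100000,,US-EPA ecotoxicity database,
propamocarb,oral,hb_geomean,116000,,US-EPA ecotoxicity database,
quinoxyfen,contact,hb_geomean,100000,,US-EPA ecotoxicity database,
quinoxyfen,oral,hb_geomean,1000000,,US-EPA ecotoxicity database,
difenoconazole,contact,hb_geomean,100000,,US-EPA ecotoxicity database,
difenoconazole,oral,hb_geomean,177000,,US-EPA ecotoxicity database,
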