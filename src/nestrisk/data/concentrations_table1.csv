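analyte,pesticide_class,chemical_group,matrix,status,mean_conc_ng_g,note
clothianidin,insecticide,neonicotinoid,soil,quantified,1.95,
clothianidin,insecticide,neonicotinoid,pollen,ND,,
clothianidin,insecticide,neonicotinoid,nectar,ND,,
imidacloprid,insecticide,neonicotinoid,soil,quantified,2.99,
imidacloprid,insecticide,neonicotinoid,pollen,quantified,4.3,
imidacloprid,insecticide,neonicotinoid,nectar,quantified,0.88,
thiamethoxam,insecticide,neonicotinoid,soil,NQ,,detected once below the limit of quantification
thiamethoxam,insecticide,neonicotinoid,pollen,ND,,
thiamethoxam,insecticide,neonicotinoid,nectar,ND,,
chlorantraniliprole,insecticide,diamide,soil,quantified,36.82,
chlorantraniliprole,insecticide,diamide,pollen,quantified,68,source table cell typographically ambiguous; value consistent with the printed adult contact HQ
chlorantraniliprole,insecticide,diamide,nectar,ND,,
carbaryl,insecticide,carbamate,soil,quantified,14.2,
carbaryl,insecticide,carbamate,pollen,quantified,16.47,
carbaryl,insecticide,carbamate,nectar,ND,,
dimethoate,insecticide,organophosphate,soil,ND,,
dimethoate,insecticide,organophosphate,pollen,quantified,6.2,
dimethoate,insecticide,organophosphate,nectar,quantified,0.5,
methomyl,insecticide,carbamate,soil,ND,,
methomyl,insecticide,carbamate,pollen,ND,,
methomyl,insecticide,carbamate,nectar,quantified,0.39,
pyraclostrobin,fungicide,strobilurin,soil,quantified,3.8,
pyraclostrobin,fungicide,strobilurin,pollen,quantified,29.65,
pyraclostrobin,fungicide,strobilurin,nectar,quantified,2,
picoxystrobin,fungicide,strobilurin,soil,ND,,
picoxystrobin,fungicide,strobilurin,pollen,quantified,4.55,
picoxystrobin,fungicide,strobilurin,nectar,quantified,0.3,
boscalid,fungicide,carboxamide,soil,quantified,46.22,
boscalid,fungicide,carboxamide,pollen,quantified,17.82,source larval HQ cell inconsistent with this value at the stated endpoint
boscalid,fungicide,carboxamide,nectar,ND,,
propamocarb,fungicide,carbamate,soil,quantified,23.03,
propamocarb,fungicide,carbamate,pollen,quantified,222.06,source larval HQ cell inconsistent with this value at the stated endpoint
propamocarb,fungicide,carbamate,nectar,quantified,11.18,
quinoxyfen,fungicide,quinoline,soil,quantified,7.86,
quinoxyfen,fungicide,quinoline,pollen,quantified,79.14,source larval HQ cell inconsistent with this value at the stated endpoint
quinoxyfen,fungicide,quinoline,nectar,ND,,
difenoconazole,fungicide,triazole,soil,quantified,18.87,
difenoconazole,fungicide,triazole,pollen,quantified,16.46,source larval HQ cell inconsistent with this value at the stated endpoint
difenoconazole,fungicide,triazole,nectar,ND,,
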