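>erabutoxin_a family=TypeI kind=anchor synthetic=1
-----------------RICVTSQSSQPTSGKECLIQDVICGNKEWHD----FRGNIEEAQCIC--PNAKPVTSGICCTNSGCEA------------------------
>alpha-cobratoxin family=TypeII kind=anchor synthetic=1
-----------------IRCVTSG---TNSGKECLIQDV-CGNKEWCDAFCTDRKKRELAQCICSKPNAKPVTSSNCCTNSGCEA-FQDVSTG----------------
>alpha-bungarotoxin family=TypeII kind=anchor synthetic=1
-----------------IRCVTSG---TNSGKECLIQDV-CGNKEWCDSHCTDRKKVELAQCICSKPNAKPVTSSNCCTNSGCEA-HQDVSTG----------------
>kappa-bungarotoxin family=TypeII kind=anchor synthetic=1
-----------------IRCVTSG---TNSGKECLIQDV-CGNKEQCDAFCTDRKKVELAQCICSKPNFRPVTSLNCCTNSGCEA------------------------
>WTX family=NonConventional kind=anchor synthetic=1
-----------------LTCVTCGI--TNCGKECLIQDVSCGNKEKHHSR---RARSWRAECIC---NALEKTSGICCTNSGCEALIQDV-------------------
>candoxin family=NonConventional kind=anchor synthetic=1
-----------------LTCVTCGI--TNCGKECLIQDVSCGNKEEHWSEA----RSARAECIC--DNALESTSGICCTNSGCEALIQD--------------------
>Oh9-1 family=Omega kind=anchor synthetic=1
-----------------TKCVTSH-----SGKECLIQDVSCGNKTTMFFPV---HPSELAQCICSKDNAKY-----CCTNSGCEALI----------------------
>fulditoxin family=Sigma kind=anchor synthetic=1
-----------------RTCVTSG----NSGKECLIQEVSCGIKELGFSHIT---NSEIATCIC-----LEVTSGICCTNSGCEALIG---------------------
>denmotoxin family=Colubrid kind=anchor synthetic=1
----------QIGSKDNTECVTCGI--TNCGKECLIQDVSCGNKEACYTLYTDGKNWAVKQCIC--PNAKPVTSGICCTNSGCEA------------------------
>TI_STD family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQSSQPTsgkeCliqdvICgnKeWhD----FRGnIeEaqCiC--PnaKPvtsgiCCtnsgCea------------------------
>TI_C4 family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQSSQPTsgkeCliqdvICgnKeWh-------GnIeEaqCiC--PnaKPvtsgiCCtnsgCea------------------------
>TI_C5 family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQ----TsgkeCliqdvICgnKeWhD-----RGnIeEaqCiC--PnaKPvtsgiCCtnsgCealiqdvst-----------------
>TI_C6 family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQ----TsgkeCliqdvICgnKeWhDsivtFRGnIeEaqCiC--PnaKPvtsgiCCtnsgCealiqdvstgnkeahlsivtdgkn--
>TI_C8 family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQSSQPTsgkeCliqdvICgnKeWhD----FRGnIeEaqCiC--PnaKPvtsgiCCtnsgCealiqdvst-----------------
>TII_STD family=TypeII kind=exemplar synthetic=1
-----------------IRCvtsg---tnsgkeCliqdv-CgnKeWCDAFCtdRkKVelaqCiCskPnaKPvtsSNCCtnsgCea-iqdvstgnkeahlsivtdgkns-
>TIII_1A family=TypeIII kind=exemplar synthetic=1
-----------------RTCvtsg----nsgkeCliqdvsCgnkeahl---tdGknsel--CiC--dnalevt---CCtnsgCealiqd--------------------
>TIII_1B family=TypeIII kind=exemplar synthetic=1
-----------------RTCvtsg----nsgkeCliqdvsCgnkeahl---td-knsel--CiC--dnalevt---CCtnsgCealiqd--------------------
>TIII_2 family=TypeIII kind=exemplar synthetic=1
-----------------RTCvtsg----nsgkeCliqdvsCgnkeahl---tdGknsel--CiC--dnalevt---CCtnsgCealiqdvstgn---------------
>NC1 family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgi--tnCgkeCliqdvsCgnkeEhWsEA----RsARaECiC--dnaleStsgiCCtnsgCealiqd--------------------
>NC2 family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgi--tnCgkeCliqdvsCgnkeEhWsEAAdAARsARaECiC------eStsgiCCtnsgCealiqd--------------------
>NC3 family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgi--tnCgkeCliqdvsCgnkeEhWsE---AARsARaECiC---naleStsgiCCtnsgCealiqdv-------------------
>NC4 family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgikqtnCgkeCliqdvsCgnkeEhWsEAAdAARsAR--CiC--dnaleStsgiCCtnsgCealiqd--------------------
>OM family=Omega kind=exemplar synthetic=1
-----------------TKCvtsH-----sgkeCliqdvsCgnKTTMFFPv---HPselaqCiCskdnaKY-----CCtnsgCeali----------------------
>SG family=Sigma kind=exemplar synthetic=1
-----------------RTCvtsg----nsgkeCliqEvsCgIkeLGFsHIt---nseIaTCiC-----levtsgiCCtnsgCealiq---------------------
>CO_STD family=Colubrid kind=exemplar synthetic=1
tdgknselaqtigskdnTECvtCgi--tnCgkeCliqdvsCgnkeaCYTLYtdgknWAVKqCiC--PnaKPvtsgiCCtnsgCealiqdvst-----------------
>CO_1B family=Colubrid kind=exemplar synthetic=1
----------tigskdnTECvtCgi--tnCgkeCliqdvsCgnkeaCYTLYtd----AVKqCiC--PnaKPvtsgiCCtnsgCea------------------------
>TI_2E family=TypeI kind=exemplar synthetic=1
-----------------RICvtsQSSQPTsgkeCliqdvICgnKeWhD-ivtFRGnIeEaqCiC--PnaKPvtsgiCCtnsgCea------------------------
>TII_X13 family=TypeII kind=exemplar synthetic=1
-----------------IRCvtsg---tnsgkeCliqdv-CgnKeWCDAFCtdR--VelaqCiCskPnaKPvtsSNCCtnsgCea-iqdvstg----------------
>NC1C family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgi--tnCgkeCliqdvsCgnkeEhWsE----HRsARaECiC--dnaleStsgiCCtnsgCealiqd--------------------
>NC3V family=NonConventional kind=exemplar synthetic=1
-----------------LTCvtCgi--tnCgkeCliqdvsCgnkeEh-sE----ARsARaECiC---naleStsgiCCtnsgCealiqdv-------------------
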