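id,publication_date,events_treat,n_treat,events_ctrl,n_ctrl,drug,drug_class,in_fda_subset
COVACTA,2020-09-12,46,226,55,226,tocilizumab,il6,True
PANAMO,2020-09-28,2,15,2,15,vilobelimab,other,False
CORIMUNO-TOCI-1,2020-10-20,16,65,18,66,tocilizumab,il6,False
RCT-TCZ,2020-10-31,26,63,18,63,tocilizumab,il6,False
EMPACTA,2020-11-19,38,194,42,195,tocilizumab,il6,True
Kumar,2020-12-15,33,90,22,90,itolizumab,other,False
REMAP-CAP-TCZ,2021-01-09,64,377,75,378,tocilizumab,il6,False
REMAP-CAP-Sarilumab,2021-01-09,45,242,41,243,sarilumab,il6,False
TOBRICAS,2021-02-02,12,30,11,30,tocilizumab,il6,False
RECOVERY,2021-02-11,502,2058,543,2058,tocilizumab,il6,True
COVINTOC,2021-03-04,16,90,18,90,tocilizumab,il6,False
Lescure-S200,2021-04-11,17,86,19,87,sarilumab,il6,False
Lescure-S400,2021-04-11,23,85,23,85,sarilumab,il6,False
REMDACTA,2021-05-06,87,324,99,325,tocilizumab,il6,True
SILCOR,2021-05-30,9,48,12,49,siltuximab,il6,False
MASH-COVID,2021-06-18,6,20,3,20,mavrilimumab,other,False
OSCAR,2021-07-03,98,403,126,403,otilimab,other,False
CORONA,2021-07-12,25,108,36,109,levilimab,other,False
LIVE-AIR,2021-07-29,55,260,59,260,lenzilumab,other,False
COVIDSTORM,2021-08-25,15,44,10,44,tocilizumab,il6,False
HMO-0224,2021-10-12,6,27,5,27,tocilizumab,il6,False
COVITOZ-01,2021-10-31,46,156,51,157,tocilizumab,il6,False
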