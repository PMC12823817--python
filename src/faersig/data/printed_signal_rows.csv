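drug,a,ror,ror_low,ror_high,prr,chi2,ebgm,ebgm05,ic,ic025
bupivacaine,31,74.05,51.95,105.54,73.45,2204.18,73.08,54.32,6.19,5.68
dalfampridine,406,23.35,21.11,25.83,23.29,8074.87,21.78,20.02,4.44,4.30
natalizumab,625,15.84,14.58,17.21,15.82,7769.42,14.27,13.31,3.83,3.71
minocycline,18,14.83,9.33,23.56,14.81,231.07,14.77,10.02,3.88,3.22
ocrelizumab,196,11.22,9.73,12.94,11.21,1762.19,10.87,9.65,3.44,3.23
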