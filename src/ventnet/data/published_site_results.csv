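site_id,simprof_group,module,z,p,betweenness,richness
DKK,4,OT,0.87,0.38,161.74,17
Ftgy,4,OT,1.01,0.22,85.73,16
HgE,4,OT,1.44,0.27,0.22,20
Higa,4,OT,0.72,0.24,1.61,14
IrbK,4,OT,0.58,0.26,2.04,13
IznC,4,OT,1.44,0.32,0.22,21
NKIR,5,OT,3.60,0.37,2.04,41
Saka,5,OT,3.60,0.37,2.04,41
SPHK,4,OT,1.73,0.18,2.04,21
SYKI,4,OT,1.01,0.12,0.22,15
TrmH,6,OT,1.01,0.00,0.00,14
TrmK,6,OT,2.02,0.16,1.61,23
MEK,3,ME,3.87,0.57,0.00,27
SmsC,2,Su,1.73,0.56,0.00,5
AlSF,1,MT,2.44,0.17,0.00,22
Arch,1,MT,0.31,0.18,0.00,10
Burk,1,MT,2.05,0.10,0.00,19
Frcs,1,MT,1.47,0.21,189.00,17
HfAd,1,MT,2.05,0.18,0.00,20
Pika,1,MT,0.89,0.00,0.00,12
Prsv,1,MT,0.70,0.00,0.00,11
Snal,1,MT,1.47,0.00,0.00,15
ByKc,9,IBMa,0.75,0.34,9.92,10
Chmv,11,IBMa,-0.20,0.00,0.50,5
Dkkv,8,IBMa,1.69,0.00,0.00,11
EsDv,8,IBMa,1.06,0.00,56.53,9
KktS,7,IBMa,0.75,0.20,30.20,9
Ks2S,8,IBMa,1.69,0.00,0.00,11
MkyS,10,IBMa,-0.83,0.00,0.00,3
MyjC,9,IBMa,0.75,0.40,91.26,11
MyjK,9,IBMa,1.69,0.42,179.36,15
Nkkv,8,IBMa,2.01,0.00,16.08,12
NrtE,11,IBMa,0.75,0.32,231.87,10
NRv,11,IBMa,-0.20,0.41,0.00,7
SmnX,11,IBMa,0.11,0.24,0.50,7
SySm,11,IBMa,-0.20,0.00,23.25,5
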