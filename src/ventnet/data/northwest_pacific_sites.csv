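site_id,name,latitude,longitude,depth_m,tectonic_setting,region
DKK,Daisan-Kume Knoll,26.302,126.413,1370,arc volcano,Ryukyu Arc
Ftgy,Futagoyama,24.867,123.308,1270,back-arc spreading center,Okinawa Trough
HgE,Higashi-Ensei,28.439,128.172,1220,back-arc spreading center,Okinawa Trough
Higa,Higa,26.555,126.223,1485,back-arc spreading center,Okinawa Trough
IrbK,Irabu Knoll,25.230,124.880,1850,back-arc spreading center,Okinawa Trough
IznC,Izena Cauldron,27.267,127.083,1610,back-arc spreading center,Okinawa Trough
NKIR,"North Knoll, Iheya Ridge",27.791,126.897,1100,back-arc spreading center,Okinawa Trough
Saka,Sakai,27.548,126.990,1600,back-arc spreading center,Okinawa Trough
SPHK,"SPOT, Hatoma Knoll",24.855,123.841,1520,back-arc spreading center,Okinawa Trough
SYKI,"SPOT, Yonaguni Knoll IV",24.849,122.700,1385,back-arc spreading center,Okinawa Trough
TrmH,Tarama Hill,25.454,124.310,1973,back-arc spreading center,Okinawa Trough
TrmK,Tarama Knoll,25.092,124.542,1990,back-arc spreading center,Okinawa Trough
MEK,Minami-Ensei Knoll,28.392,127.642,740,back-arc spreading center,Okinawa Trough
SmsC,Sumisu Caldera,31.467,140.067,690,arc volcano,Izu-Bonin Arc
AlSF,Alice Springs Field,18.210,144.707,3640,back-arc spreading center,Mariana Trough
Arch,Archaean,12.939,143.632,3060,back-arc spreading center,Mariana Trough
Burk,Burke,18.109,144.432,3660,back-arc spreading center,Mariana Trough
Frcs,Forecast,13.400,143.917,1470,back-arc spreading center,Mariana Trough
HfAd,Hafa Adai,16.957,144.868,3294,back-arc spreading center,Mariana Trough
Pika,Pika,12.918,143.648,2990,back-arc spreading center,Mariana Trough
Prsv,Perseverance,15.480,144.508,3935,back-arc spreading center,Mariana Trough
Snal,Snail,12.953,143.620,2880,back-arc spreading center,Mariana Trough
ByKc,Bayonnaise Knoll caldera,31.967,139.733,900,back-arc spreading center,Izu-Bonin back-arc
Chmv,Chamorro volcano,20.810,144.705,896,arc volcano,Mariana Arc
Dkkv,Daikoku volcano,21.324,144.194,450,arc volcano,Mariana Arc
EsDv,East Diamante volcano,15.930,145.670,457,arc volcano,Mariana Arc
KktS,Kaikata Seamount,26.700,141.083,930,arc volcano,Izu-Bonin Arc
Ks2S,Kasuga 2 Seamount,21.600,143.617,500,arc volcano,Mariana Arc
MkyS,Mokuyo Seamount,28.320,140.580,1200,arc volcano,Izu-Bonin Arc
MyjC,Myojinsho Caldera,31.883,139.950,1110,arc volcano,Izu-Bonin Arc
MyjK,Myojin Knoll,32.103,139.868,1360,arc volcano,Izu-Bonin Arc
Nkkv,Nikko volcano,23.083,142.333,600,arc volcano,Mariana Arc
NrtE,Northwest Eifuku,21.485,144.043,1604,arc volcano,Mariana Arc
NRv,Northwest Rota-1 volcano,14.601,144.775,599,arc volcano,Mariana Arc
SmnX,Seamount X,13.250,144.020,1450,arc volcano,Mariana Arc
SySm,Suiyo Seamount,28.575,140.642,1380,arc volcano,Izu-Bonin Arc
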