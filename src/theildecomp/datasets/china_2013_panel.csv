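unit,year,population_10k,area_10k_km2,institutions,personnel,beds,investment_100m_yuan
Shanghai,2013,2415,0.63,4926.6,157095.75,114301.95,217.35
Tianjin,2013,1472,1.13,4695.68,81077.76,57687.68,132.48
Jiangsu,2013,7939,10.26,30962.1,428864.78,368290.21,476.34
Anhui,2013,6030,13.97,24662.7,253561.5,236014.2,361.8
Guangdong,2013,10644,18,47791.56,553700.88,378394.2,532.2
Beijing,2013,2115,1.68,9686.7,203759.1,104015.7,274.95
Yunnan,2013,4687,38.33,24278.66,193245.01,210118.21,281.22
Zhejiang,2013,5498,10.2,30074.06,352476.78,230091.3,329.88
Heilongjiang,2013,3835,45.48,21360.95,207588.55,189180.55,191.75
Hainan,2013,895,3.40,5012,48097.3,32085.75,71.6
Hubei,2013,5799,18.59,35605.86,309318.66,288210.3,347.94
Chongqing,2013,2970,8.23,18918.9,142144.2,147401.1,207.9
Ningxia,2013,654,6.64,4231.38,37278,31091.16,52.32
Guangxi,2013,4719,23.6,33929.61,240904.95,187202.73,283.14
Jilin,2013,2751,18.74,19917.24,145913.04,133175.91,192.57
Fujian,2013,3774,12.13,28191.78,197531.16,156092.64,226.44
Henan,2013,9413,16.7,71444.67,468485.01,429797.58,470.65
Shandong,2013,9733,15.38,75430.75,596924.89,489667.23,486.65
Liaoning,2013,4390,14.59,35602.9,254707.8,241889,219.5
Xinjiang,2013,2264,166.00,18655.36,145824.24,137288.96,158.48
Guizhou,2013,3502,17.60,29171.66,155909.04,166695.2,245.14
Jiangxi,2013,4522,16.70,38889.2,190104.88,174277.88,271.32
Hunan,2013,6691,21.18,62226.3,323108.39,314142.45,334.55
Inner Mongolia,2013,2498,118.3,23256.38,148231.32,120128.82,199.84
Sichuan,2013,8107,48.14,80016.09,426995.69,426590.34,486.42
Shaanxi,2013,3764,20.56,37150.68,239051.64,185113.52,263.48
Gansu,2013,2582,45.44,26697.88,118074.86,116086.72,154.92
Qinghai,2013,578,72.23,6022.76,32443.14,29512.68,69.36
Hebei,2013,7333,18.77,78463.1,333064.86,303512.87,366.65
Shanxi,2013,3630,15.63,40293,203388.9,172606.5,217.8
Tibet,2013,312,122.80,6723.6,11637.6,10998,40.56
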