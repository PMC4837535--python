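unit,region
Shanghai,east
Tianjin,east
Jiangsu,east
Anhui,central
Guangdong,east
Beijing,east
Yunnan,west
Zhejiang,east
Heilongjiang,central
Hainan,east
Hubei,central
Chongqing,west
Ningxia,west
Guangxi,west
Jilin,central
Fujian,east
Henan,central
Shandong,east
Liaoning,east
Xinjiang,west
Guizhou,west
Jiangxi,central
Hunan,central
Inner Mongolia,west
Sichuan,west
Shaanxi,west
Gansu,west
Qinghai,west
Hebei,east
Shanxi,central
Tibet,west
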