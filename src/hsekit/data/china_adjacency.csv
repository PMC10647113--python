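unit_a,unit_b
Beijing,Tianjin
Beijing,Hebei
Tianjin,Hebei
Hebei,Liaoning
Hebei,Inner Mongolia
Hebei,Shanxi
Hebei,Henan
Hebei,Shandong
Shanxi,Inner Mongolia
Shanxi,Shaanxi
Shanxi,Henan
Inner Mongolia,Heilongjiang
Inner Mongolia,Jilin
Inner Mongolia,Liaoning
Inner Mongolia,Shaanxi
Inner Mongolia,Ningxia
Inner Mongolia,Gansu
Liaoning,Jilin
Jilin,Heilongjiang
Shanghai,Jiangsu
Shanghai,Zhejiang
Jiangsu,Zhejiang
Jiangsu,Anhui
Jiangsu,Shandong
Zhejiang,Anhui
Zhejiang,Jiangxi
Zhejiang,Fujian
Anhui,Jiangxi
Anhui,Hubei
Anhui,Henan
Anhui,Shandong
Fujian,Jiangxi
Fujian,Guangdong
Jiangxi,Guangdong
Jiangxi,Hunan
Jiangxi,Hubei
Shandong,Henan
Henan,Shaanxi
Henan,Hubei
Hubei,Shaanxi
Hubei,Chongqing
Hubei,Hunan
Hunan,Chongqing
Hunan,Guizhou
Hunan,Guangxi
Hunan,Guangdong
Guangdong,Guangxi
Guangdong,Hainan
Guangxi,Guizhou
Guangxi,Yunnan
Chongqing,Shaanxi
Chongqing,Guizhou
Chongqing,Sichuan
Sichuan,Shaanxi
Sichuan,Gansu
Sichuan,Qinghai
Sichuan,Tibet
Sichuan,Yunnan
Sichuan,Guizhou
Guizhou,Yunnan
Yunnan,Tibet
Tibet,Xinjiang
Tibet,Qinghai
Shaanxi,Gansu
Shaanxi,Ningxia
Gansu,Xinjiang
Gansu,Qinghai
Gansu,Ningxia
Qinghai,Xinjiang
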