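region_id,year,indicator,density_per_1000
Guangxi,2014,beds,4.42
Guangxi,2014,physicians,1.82
Guangxi,2014,nurses,2.19
Guangxi,2015,beds,4.47
Guangxi,2015,physicians,1.90
Guangxi,2015,nurses,2.40
Guangxi,2016,beds,4.46
Guangxi,2016,physicians,2.00
Guangxi,2016,nurses,2.53
Guangxi,2017,beds,4.94
Guangxi,2017,physicians,2.07
Guangxi,2017,nurses,2.70
Guangxi,2018,beds,5.20
Guangxi,2018,physicians,2.15
Guangxi,2018,nurses,2.85
Shaanxi,2014,beds,5.28
Shaanxi,2014,physicians,2.03
Shaanxi,2014,nurses,2.58
Shaanxi,2015,beds,5.59
Shaanxi,2015,physicians,2.10
Shaanxi,2015,nurses,2.80
Shaanxi,2016,beds,5.91
Shaanxi,2016,physicians,2.25
Shaanxi,2016,nurses,3.06
Shaanxi,2017,beds,6.29
Shaanxi,2017,physicians,2.43
Shaanxi,2017,nurses,3.31
Shaanxi,2018,beds,6.57
Shaanxi,2018,physicians,2.56
Shaanxi,2018,nurses,3.57
Gansu,2014,beds,4.72
Gansu,2014,physicians,1.84
Gansu,2014,nurses,1.75
Gansu,2015,beds,4.91
Gansu,2015,physicians,1.90
Gansu,2015,nurses,1.80
Gansu,2016,beds,5.15
Gansu,2016,physicians,2.02
Gansu,2016,nurses,1.94
Gansu,2017,beds,5.58
Gansu,2017,physicians,2.14
Gansu,2017,nurses,2.23
Gansu,2018,beds,6.17
Gansu,2018,physicians,2.26
Gansu,2018,nurses,2.44
Qinghai,2014,beds,5.66
Qinghai,2014,physicians,2.22
Qinghai,2014,nurses,2.19
Qinghai,2015,beds,5.87
Qinghai,2015,physicians,2.30
Qinghai,2015,nurses,2.20
Qinghai,2016,beds,5.86
Qinghai,2016,physicians,2.30
Qinghai,2016,nurses,2.42
Qinghai,2017,beds,6.41
Qinghai,2017,physicians,2.59
Qinghai,2017,nurses,2.76
Qinghai,2018,beds,6.49
Qinghai,2018,physicians,2.68
Qinghai,2018,nurses,2.91
Ningxia,2014,beds,4.91
Ningxia,2014,physicians,2.27
Ningxia,2014,nurses,2.28
Ningxia,2015,beds,5.06
Ningxia,2015,physicians,2.40
Ningxia,2015,nurses,2.40
Ningxia,2016,beds,5.38
Ningxia,2016,physicians,2.53
Ningxia,2016,nurses,2.68
Ningxia,2017,beds,5.84
Ningxia,2017,physicians,2.67
Ningxia,2017,nurses,3.16
Ningxia,2018,beds,5.96
Ningxia,2018,physicians,2.82
Ningxia,2018,nurses,3.38
Xinjiang,2014,beds,6.22
Xinjiang,2014,physicians,2.38
Xinjiang,2014,nurses,2.60
Xinjiang,2015,beds,6.37
Xinjiang,2015,physicians,2.40
Xinjiang,2015,nurses,2.70
Xinjiang,2016,beds,6.54
Xinjiang,2016,physicians,2.51
Xinjiang,2016,nurses,2.82
Xinjiang,2017,beds,6.85
Xinjiang,2017,physicians,2.55
Xinjiang,2017,nurses,2.89
Xinjiang,2018,beds,7.19
Xinjiang,2018,physicians,2.55
Xinjiang,2018,nurses,2.91
Sichuan,2014,beds,5.65
Sichuan,2014,physicians,2.21
Sichuan,2014,nurses,2.16
Sichuan,2015,beds,5.96
Sichuan,2015,physicians,2.20
Sichuan,2015,nurses,2.30
Sichuan,2016,beds,6.28
Sichuan,2016,physicians,2.24
Sichuan,2016,nurses,2.51
Sichuan,2017,beds,6.79
Sichuan,2017,physicians,2.35
Sichuan,2017,nurses,2.75
Sichuan,2018,beds,7.18
Sichuan,2018,physicians,2.46
Sichuan,2018,nurses,2.96
Chongqing,2014,beds,5.37
Chongqing,2014,physicians,1.94
Chongqing,2014,nurses,1.32
Chongqing,2015,beds,5.85
Chongqing,2015,physicians,2.00
Chongqing,2015,nurses,2.30
Chongqing,2016,beds,6.26
Chongqing,2016,physicians,2.12
Chongqing,2016,nurses,2.54
Chongqing,2017,beds,6.71
Chongqing,2017,physicians,2.23
Chongqing,2017,nurses,2.76
Chongqing,2018,beds,7.10
Chongqing,2018,physicians,2.46
Chongqing,2018,nurses,3.07
Yunnan,2014,beds,4.77
Yunnan,2014,physicians,1.60
Yunnan,2014,nurses,1.23
Yunnan,2015,beds,5.01
Yunnan,2015,physicians,1.70
Yunnan,2015,nurses,2.00
Yunnan,2016,beds,5.31
Yunnan,2016,physicians,1.80
Yunnan,2016,nurses,2.22
Yunnan,2017,beds,5.72
Yunnan,2017,physicians,1.96
Yunnan,2017,nurses,2.68
Yunnan,2018,beds,6.03
Yunnan,2018,physicians,2.06
Yunnan,2018,nurses,2.83
Guizhou,2014,beds,5.19
Guizhou,2014,physicians,1.65
Guizhou,2014,nurses,1.92
Guizhou,2015,beds,5.57
Guizhou,2015,physicians,1.80
Guizhou,2015,nurses,2.20
Guizhou,2016,beds,5.92
Guizhou,2016,physicians,1.94
Guizhou,2016,nurses,2.42
Guizhou,2017,beds,6.51
Guizhou,2017,physicians,2.11
Guizhou,2017,nurses,2.74
Guizhou,2018,beds,6.82
Guizhou,2018,physicians,2.26
Guizhou,2018,nurses,3.03
Inner Mongolia,2014,beds,5.15
Inner Mongolia,2014,physicians,2.48
Inner Mongolia,2014,nurses,2.26
Inner Mongolia,2015,beds,5.33
Inner Mongolia,2015,physicians,2.60
Inner Mongolia,2015,nurses,1.90
Inner Mongolia,2016,beds,5.53
Inner Mongolia,2016,physicians,2.63
Inner Mongolia,2016,nurses,2.64
Inner Mongolia,2017,beds,5.94
Inner Mongolia,2017,physicians,2.78
Inner Mongolia,2017,nurses,2.84
Inner Mongolia,2018,beds,6.27
Inner Mongolia,2018,physicians,2.90
Inner Mongolia,2018,nurses,3.02
Tibet,2014,beds,3.75
Tibet,2014,physicians,1.76
Tibet,2014,nurses,1.43
Tibet,2015,beds,4.33
Tibet,2015,physicians,1.90
Tibet,2015,nurses,1.00
Tibet,2016,beds,4.37
Tibet,2016,physicians,1.98
Tibet,2016,nurses,1.16
Tibet,2017,beds,4.78
Tibet,2017,physicians,2.26
Tibet,2017,nurses,1.32
Tibet,2018,beds,4.88
Tibet,2018,physicians,2.42
Tibet,2018,nurses,1.62
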