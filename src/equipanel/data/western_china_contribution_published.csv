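dimension,year,indicator,between_pct,within_pct
population,2014,beds,8.00,92.00
population,2014,physicians,10.31,89.69
population,2014,nurses,8.82,91.18
population,2015,beds,12.53,87.47
population,2015,physicians,14.15,85.85
population,2015,nurses,6.90,93.10
population,2016,beds,18.68,81.32
population,2016,physicians,15.69,84.31
population,2016,nurses,2.96,97.04
population,2017,beds,23.72,76.28
population,2017,physicians,10.68,89.32
population,2017,nurses,0.12,99.88
population,2018,beds,26.75,73.25
population,2018,physicians,4.18,95.82
population,2018,nurses,2.57,97.43
geographic,2014,beds,36.95,63.05
geographic,2014,physicians,32.04,67.96
geographic,2014,nurses,29.87,70.13
geographic,2015,beds,36.99,63.01
geographic,2015,physicians,31.80,68.20
geographic,2015,nurses,30.01,69.99
geographic,2016,beds,37.21,62.79
geographic,2016,physicians,31.77,68.23
geographic,2016,nurses,30.55,69.45
geographic,2017,beds,37.55,62.45
geographic,2017,physicians,32.57,67.43
geographic,2017,nurses,32.26,67.74
geographic,2018,beds,37.71,62.29
geographic,2018,physicians,33.09,66.91
geographic,2018,nurses,32.85,67.15
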