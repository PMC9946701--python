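dimension,year,indicator,theil_total,theil_within,theil_between
population,2014,beds,0.002,0.002,0.000
population,2014,physicians,0.004,0.004,0.000
population,2014,nurses,0.004,0.004,0.000
population,2015,beds,0.002,0.002,0.000
population,2015,physicians,0.003,0.003,0.000
population,2015,nurses,0.003,0.003,0.000
population,2016,beds,0.002,0.002,0.000
population,2016,physicians,0.003,0.002,0.000
population,2016,nurses,0.003,0.003,0.000
population,2017,beds,0.002,0.002,0.001
population,2017,physicians,0.002,0.002,0.000
population,2017,nurses,0.002,0.002,0.000
population,2018,beds,0.002,0.002,0.001
population,2018,physicians,0.002,0.002,0.000
population,2018,nurses,0.002,0.002,0.000
geographic,2014,beds,0.318,0.200,0.117
geographic,2014,physicians,0.300,0.204,0.096
geographic,2014,nurses,0.228,0.097,0.228
geographic,2015,beds,0.321,0.202,0.119
geographic,2015,physicians,0.299,0.204,0.095
geographic,2015,nurses,0.230,0.099,0.230
geographic,2016,beds,0.326,0.205,0.121
geographic,2016,physicians,0.301,0.206,0.096
geographic,2016,nurses,0.231,0.102,0.231
geographic,2017,beds,0.326,0.204,0.122
geographic,2017,physicians,0.300,0.202,0.098
geographic,2017,nurses,0.227,0.108,0.227
geographic,2018,beds,0.326,0.203,0.123
geographic,2018,physicians,0.306,0.205,0.101
geographic,2018,nurses,0.227,0.111,0.227
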