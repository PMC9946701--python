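dimension,year,indicator,gini
population,2014,beds,0.0583
population,2014,physicians,0.0785
population,2014,nurses,0.0719
geographic,2014,beds,0.6275
geographic,2014,physicians,0.6151
geographic,2014,nurses,0.6359
population,2015,beds,0.0577
population,2015,physicians,0.0694
population,2015,nurses,0.0644
geographic,2015,beds,0.6300
geographic,2015,physicians,0.6136
geographic,2015,nurses,0.6388
population,2016,beds,0.0584
population,2016,physicians,0.0601
population,2016,nurses,0.0611
geographic,2016,beds,0.6338
geographic,2016,physicians,0.6158
geographic,2016,nurses,0.6421
population,2017,beds,0.0580
population,2017,physicians,0.0578
population,2017,nurses,0.0438
geographic,2017,beds,0.6344
geographic,2017,physicians,0.6149
geographic,2017,nurses,0.6433
population,2018,beds,0.0574
population,2018,physicians,0.0525
population,2018,nurses,0.0462
geographic,2018,beds,0.6343
geographic,2018,physicians,0.6200
geographic,2018,nurses,0.6469
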