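year,population_10k,institutions,institutions_per_10k,personnel,personnel_per_10k,beds,beds_per_10k,investment_100m_yuan,investment_per_10k
2009,133450,916571,6.87,5535124,41.48,4416612,33.10,3930.69,0.03
2010,134091,936927,6.99,5866158,43.75,4786831,35.70,4730.62,0.04
2011,134735,954389,7.08,6192858,45.96,5159889,38.30,6358.20,0.05
2012,135404,950297,7.02,6668549,49.25,5724775,42.28,7170.81,0.05
2013,136072,974398,7.16,7200578,52.92,6181891,45.43,8203.20,0.06
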