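marlin_id,weight_kg,start_date,start_lat,start_lon,end_lat,end_lon,days_at_liberty,slrt_days,psat_days,max_gap_days,flag
STM05.2,85,2005-02-25,-37.244,176.103,-31.245,173.185,21,9,21,11.0,
STM05.3,100,2005-02-26,-37.295,176.273,-29.506,180.460,21,21,21,2.5,
STM05.4,70,2005-03-18,-37.069,176.039,-21.703,176.134,60,25,60,2.0,
STM06.1,74,2006-01-10,-32.635,167.563,-31.897,167.068,68,25,68,1.0,archival_recovered
STM06.2,80,2006-01-11,-31.683,167.833,-31.368,168.824,15,1,15,4.1,
STM06.3,81,2006-01-12,-31.707,167.835,-33.013,167.582,103,21,103,11.0,
STM06.4,66,2006-01-13,-31.744,167.880,-33.443,180.484,28,28,0,4.1,no_transmit
STM06.5,110,2006-02-04,-36.513,173.629,-24.105,167.376,80,21,80,41.0,
STM06.6,66,2006-02-20,-37.646,177.813,-24.191,177.850,65,23,65,2.3,
STM06.7,66,2006-03-01,-37.397,176.374,-24.552,182.792,85,43,85,19.0,
STM06.8,65,2006-03-31,-31.706,167.846,-20.217,168.878,28,28,0,14.1,no_transmit
STM06.9,81,2006-02-13,-34.858,173.757,-32.638,173.053,17,17,0,6.4,no_transmit
STM06.10,75,2006-03-31,-31.706,167.846,-21.717,161.812,133,36,133,7.0,
STM06.11,95,2006-03-31,-31.707,167.852,-23.757,175.176,68,25,68,12.0,
STM06.12,80,2006-04-02,-31.709,167.833,-26.220,170.119,34,17,34,2.0,archival_recovered
STM06.13,90,2006-04-03,-31.667,167.817,-26.275,172.453,29,15,29,2.0,
STM06.14,80,2006-04-03,-31.683,167.850,-21.817,170.404,100,26,100,3.0,
STM06.15,76,2006-04-04,-31.699,167.845,-27.179,166.796,18,18,0,2.3,no_transmit
STM07.1,85,2007-02-19,-37.485,177.982,-20.111,225.358,103,103,0,6.7,slrt_only
STM07.2,60,2007-02-19,-37.408,178.344,-30.682,182.985,59,59,0,19.8,slrt_only
STM07.3,75,2007-02-20,-37.509,177.847,-25.628,169.307,50,50,0,2.0,slrt_only
STM07.4,100,2007-02-20,-37.560,177.660,-27.422,202.586,91,33,91,7.0,
STM07.5,80,2007-02-21,-37.373,177.754,-34.448,180.691,18,18,0,1.6,slrt_only
STM08.1,80,2008-03-06,-37.449,177.964,-22.119,182.035,115,115,0,6.2,no_transmit
STM08.2,75,2008-03-08,-37.509,178.073,-27.701,179.716,22,22,0,1.5,no_transmit
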