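specimen_id,species,sex,specimen_type,year_of_death,layer_index,year,pmc,pmc_sd,d13c,d13c_sd,d15n,d15n_sd,lab_id
4076,narwhal,M,tusk,2008,11,1960,98.28,0.51,,,,,
4076,narwhal,M,tusk,2008,12,1961,100.69,0.38,,,,,
4076,narwhal,M,tusk,2008,11,1960,99.55,0.40,,,,,
4076,narwhal,M,tusk,2008,14,1963,100.92,0.38,,,,,
4076,narwhal,M,tusk,2008,22,1971,103.31,0.49,,,,,
4076,narwhal,M,tusk,2008,33,1982,104.26,0.39,,,,,
4076,narwhal,M,tusk,2008,48,1997,102.36,0.39,,,,,
4076,narwhal,M,tusk,2008,11,1960,99.03,0.34,-14.5,0.2,17.5,0.4,AAR-31974
4076,narwhal,M,tusk,2008,12,1961,99.96,0.30,-14.9,0.2,17.6,0.4,AAR-31975
4076,narwhal,M,tusk,2008,13,1962,100.52,0.28,-14.5,0.2,17.2,0.2,AAR-31976
4076,narwhal,M,tusk,2008,17,1966,99.84,0.27,-14.7,0.2,17.6,0.4,AAR-31977
4076,narwhal,M,tusk,2008,20,1969,101.21,0.31,-14.2,0.2,18.0,0.4,AAR-31978
4076,narwhal,M,tusk,2008,21,1970,101.02,0.32,-13.9,0.2,18.8,0.2,AAR-31979
4076,narwhal,M,tusk,2008,22,1971,101.78,0.29,-13.7,0.2,18.1,0.4,AAR-31980
4076,narwhal,M,tusk,2008,32,1981,103.62,0.31,-13.7,0.2,18.7,0.4,AAR-31981
4076,narwhal,M,tusk,2008,44,1993,103.60,0.29,-13.8,0.2,19.5,0.4,AAR-31982
4076,narwhal,M,tusk,2008,54,2003,103.15,0.34,-13.9,0.2,19.3,0.4,AAR-31983
956,narwhal,M,tusk,2010,1,1958,94.87,0.26,-14.2,0.2,17.4,0.4,AAR-31984
956,narwhal,M,tusk,2010,2,1959,96.84,0.28,-14.1,0.2,17.2,0.2,AAR-31985
956,narwhal,M,tusk,2010,3,1960,98.33,0.28,-14.2,0.2,16.8,0.4,AAR-31986
956,narwhal,M,tusk,2010,5,1962,100.21,0.27,-14.2,0.2,16.6,0.4,AAR-31987
956,narwhal,M,tusk,2010,7,1964,100.54,0.28,-14.3,0.2,16.4,0.4,AAR-31988
956,narwhal,M,tusk,2010,9,1966,98.61,0.31,-14.0,0.2,17.0,0.4,AAR-31989
956,narwhal,M,tusk,2010,12,1969,100.29,0.31,-14.4,0.2,16.8,0.4,AAR-31990
956,narwhal,M,tusk,2010,23,1980,102.91,0.27,-14.2,0.2,16.8,0.4,AAR-31991
956,narwhal,M,tusk,2010,35,1992,103.69,0.29,-14.1,0.2,18.6,0.2,AAR-31992
956,narwhal,M,tusk,2010,45,2002,103.37,0.29,-14.5,0.2,17.6,0.4,AAR-31993
953,narwhal,M,tusk,2008,1,1982,106.01,0.40,,,,,
953,narwhal,M,tusk,2008,6,1987,105.49,0.40,,,,,
953,narwhal,M,tusk,2008,16,1997,103.84,0.44,,,,,
1269,narwhal,F,tooth,1984,0,1958,95.57,0.30,-14.5,0.2,21.0,0.1,AAR-35621
1269,narwhal,F,tooth,1984,10,1968,101.28,0.36,-14.9,0.2,17.4,0.1,AAR-35622
1229,narwhal,F,tooth,1984,0,1975,101.31,0.38,-14.7,0.2,19.8,0.1,AAR-35623
1229,narwhal,F,tooth,1984,9,1984,103.16,0.34,-14.7,0.1,17.6,0.1,AAR-35624
1336,narwhal,M,tooth,1985,0,1938,92.65,0.39,-14.8,0.2,20.1,0.1,AAR-35625
1336,narwhal,M,tooth,1985,20,1958,94.12,0.38,-14.6,0.2,17.7,0.1,AAR-35626
1338,narwhal,M,tooth,1985,0,1942,92.68,0.33,-14.0,0.2,20.3,0.1,AAR-35627
1338,narwhal,M,tooth,1985,16,1958,94.32,0.57,-14.5,0.2,17.8,0.1,AAR-35628
560,narwhal,F,tooth,1993,0,1925,92.66,0.36,-14.7,0.1,20.7,0.1,AAR-35629
560,narwhal,F,tooth,1993,10,1935,91.81,0.38,-14.8,0.2,18.4,0.1,AAR-35630
537,narwhal,F,tooth,1993,0,1945,92.47,0.30,-15.3,0.2,20.0,0.1,AAR-35631
537,narwhal,F,tooth,1993,11,1956,93.26,0.36,-14.3,0.2,18.3,0.1,AAR-35632
562,narwhal,F,tooth,1993,0,1892,93.27,0.35,-14.4,0.2,20.5,0.1,AAR-35633
562,narwhal,F,tooth,1993,10,1902,92.92,0.34,-14.1,0.2,18.3,0.1,AAR-35634
559,narwhal,F,tooth,1993,0,1930,93.36,0.32,-14.4,0.2,20.3,0.1,AAR-35635
559,narwhal,F,tooth,1993,10,1940,93.20,0.35,-14.4,0.1,17.9,0.1,AAR-35636
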