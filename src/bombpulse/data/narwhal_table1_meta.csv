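specimen_id,species,sex,specimen_type,year_of_death,layers_counted,layers_missing_lo,layers_missing_hi,neonatal_line
4076,narwhal,M,tusk,2008,60,10,10,absent
956,narwhal,M,tusk,2010,70,1,3,absent
953,narwhal,M,tusk,2008,26,0,0,uncertain
1336,narwhal,M,tooth,1985,20,0,0,present
1338,narwhal,M,tooth,1985,16,0,0,present
560,narwhal,F,tooth,1993,10,0,0,present
537,narwhal,F,tooth,1993,11,0,0,present
562,narwhal,F,tooth,1993,10,0,0,present
559,narwhal,F,tooth,1993,10,0,0,present
1269,narwhal,F,tooth,1984,10,0,0,present
1229,narwhal,F,tooth,1984,9,0,0,present
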