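name	sequence	aat_celsius
SA-1	G CAC ATG ACC ATI CAR ACY GC	60
SA-4	CC GGT IGC GCA ICC MAR GTT	
GI-1	GAT TTG GGI CCI GTY ATG GT	55
GI-2	TG TTG IAI GTA RGC WGG GAA	
PG-1	TC AGI GTY GAC TTC AAC GTC CC	55
PG-2	GAA IGT GAA RGC CAT ACC ACC	
DE-1	CAC GAT GTI GGT GCT GGT GG	60
DE-2	GC AAC IGG IAC YTG CCA AGG	
ME-1	C GAT ATG GTT CAI TAC TTY GGT GA	50
ME-2	AT GGA AAS IAC ITC RGC ATC	
AT-1	GCT ATG GAI GGT ACI GAR GG	55
AT-2	AC GGC AGA KGG AAT ACG ACC	
GC-1	ATC GGI CAI GTM GCC CAC GG	-
GC-2	GA ACC ACC IGC AAC ACC WCC	
FS-1	CAA GAI CAR GGY ATG GGT ATG GA	50
FS-2	TC ACC IAI AGA RTG ACC AGC	
PA-1	GGT AAG GGT GGI TCI ATG CA	-
PA-2	AC AGA CAT IGA ITG RCC ACC	
VM-1	AAG GIT GTI CAY GAT GGT CA	50
VM-2	GT CAT ICC ITC ACC RAT RGC	
EC-1	GYY GGT GGT GGT ATG GG	-
EC-2	GG RCA ACC AGT CAT ICK CAT	
OL-1	GAT GTI GCS TCI ATG TAY CC	50
OL-2	GC CAT TTC IAT SGA RTA CCA	
LT-1	ATG GAR CCI TGG GAT GGY CC	55
LT-4	GG IGG ATT IGT SAC YTG AGC	
LT-5	GCA CCI TGY GAI GGI GCT TG	50
LT-6	CA ATC ITT ACC IGT RTC ACC	
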