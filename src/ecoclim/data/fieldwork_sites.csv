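name,lat,lon,area_m2,observed,evidence
Sanya,18.14,109.31,90,perennial,all stages found throughout the year
Guangzhou,23.16,113.23,300,perennial,all stages found throughout the year
Longnan,24.91,114.79,200,overwinter,living larva on Brassica oleracea var. capitata (1) Jan 2010
Nanchang,28.68,115.89,500,overwinter,living larvae on Raphanus sativus (6) Jan 2010; pupae (5)
Yongxiu,29.04,115.82,2000,overwinter,living larva on Brassica rapa pekinensis (1) Jan 2010
Yibin,29.77,104.56,3000,overwinter,living pupa on Allium schoenoprasum (1); pheromone-trapped adults Jan-Mar 2010
Wuhan,30.5,114.3,20000,overwinter,living larvae on Spinacia oleracea (22) 12 Jan 2009; Brassica compestris (1) Mar 2009
Jurong,31.95,119.16,5000,none,no individuals found during winter
Nanjing,32.04,118.78,3000,none,no individuals found during winter
Xi'an,34.27,108.95,500,none,no individuals found during winter
Tai'an,36.18,117.13,,none,no individuals found during winter
Anqiu,36.42,119.2,,none,no individuals found during winter
Zhangqiu,36.72,117.53,,none,no individuals found during winter
Beijing,39.92,116.46,,none,no individuals found during winter
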