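name,age_base,age_top,is_mass_extinction,is_recovery
Tremadocian,485.4,477.7,0,0
Floian,477.7,470.0,0,0
Dapingian,470.0,467.3,0,0
Darriwilian,467.3,458.4,0,0
Sandbian,458.4,453.0,0,0
Katian,453.0,445.2,0,0
Hirnantian,445.2,443.8,1,0
Rhuddanian,443.8,440.8,0,1
Aeronian,440.8,438.5,0,0
Telychian,438.5,433.4,0,0
Sheinwoodian,433.4,430.5,0,0
Homerian,430.5,427.4,0,0
Gorstian,427.4,425.6,0,0
Ludfordian,425.6,423.0,0,0
Pridoli,423.0,419.2,0,0
Lochkovian,419.2,410.8,0,0
Pragian,410.8,407.6,0,0
Emsian,407.6,393.3,0,0
Eifelian,393.3,387.7,0,0
Givetian,387.7,382.7,0,0
Frasnian,382.7,372.2,1,0
Famennian,372.2,358.9,0,1
Tournaisian,358.9,346.7,0,0
Visean,346.7,330.9,0,0
Serpukhovian,330.9,323.2,0,0
Bashkirian,323.2,315.2,0,0
Moscovian,315.2,307.0,0,0
Kasimovian,307.0,303.7,0,0
Gzhelian,303.7,298.9,0,0
Asselian,298.9,293.5,0,0
Sakmarian,293.5,290.1,0,0
Artinskian,290.1,283.5,0,0
Kungurian,283.5,273.0,0,0
Roadian,273.0,266.9,0,0
Wordian,266.9,264.3,0,0
Capitanian,264.3,259.5,0,0
Wuchiapingian,259.5,254.1,0,0
Changhsingian,254.1,251.9,1,0
Induan,251.9,251.2,0,1
Olenekian,251.2,247.2,0,0
Anisian,247.2,242.0,0,0
Ladinian,242.0,237.0,0,0
Carnian,237.0,227.0,0,0
Norian,227.0,208.5,0,0
Rhaetian,208.5,201.4,1,0
Hettangian,201.4,199.5,0,1
Sinemurian,199.5,192.9,0,0
Pliensbachian,192.9,184.2,0,0
Toarcian,184.2,174.7,0,0
Aalenian,174.7,170.9,0,0
Bajocian,170.9,168.2,0,0
Bathonian,168.2,165.3,0,0
Callovian,165.3,161.5,0,0
Oxfordian,161.5,154.8,0,0
Kimmeridgian,154.8,149.2,0,0
Tithonian,149.2,145.0,0,0
Berriasian,145.0,139.8,0,0
Valanginian,139.8,132.6,0,0
Hauterivian,132.6,125.8,0,0
Barremian,125.8,121.4,0,0
Aptian,121.4,113.0,0,0
Albian,113.0,100.5,0,0
Cenomanian,100.5,93.9,0,0
Turonian,93.9,89.8,0,0
Coniacian,89.8,86.3,0,0
Santonian,86.3,83.6,0,0
Campanian,83.6,72.1,0,0
Maastrichtian,72.1,66.0,1,0
Danian,66.0,61.6,0,1
Selandian,61.6,59.2,0,0
Thanetian,59.2,56.0,0,0
Ypresian,56.0,47.8,0,0
Lutetian,47.8,41.2,0,0
Bartonian,41.2,37.71,0,0
Priabonian,37.71,33.9,0,0
Rupelian,33.9,27.82,0,0
Chattian,27.82,23.03,0,0
Aquitanian,23.03,20.44,0,0
Burdigalian,20.44,15.97,0,0
Langhian,15.97,13.82,0,0
Serravallian,13.82,11.63,0,0
Tortonian,11.63,7.246,0,0
Messinian,7.246,5.333,0,0
Zanclean,5.333,3.6,0,0
Piacenzian,3.6,2.58,0,0
Gelasian,2.58,1.8,0,0
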