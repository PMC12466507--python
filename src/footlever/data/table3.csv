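order,family,species,common_name,theta_obs_deg,theta_est_deg,sin_alpha,body_mass_kg,locomotor_mode
Artiodactyla,Bovidae,Ammotragus lervia,Barbary sheep,142,130,0.98,64,unguligrade
Artiodactyla,Bovidae,Capra hircus,goat,130,137,0.99,20,unguligrade
Artiodactyla,Bovidae,Capricornis crispus,Japanese serow,127,127,1.00,38,unguligrade
Artiodactyla,Cervidae,Cervus nippon yesoensis,Yezo shika deer,126,123,0.99,75,unguligrade
Artiodactyla,Cervidae,Rangifer tarandus,reindeer,122,121,1.00,120,unguligrade
Artiodactyla,Giraffidae,Giraffa reticulata,reticulated giraffe,146,140,0.99,1000,unguligrade
Artiodactyla,Hippopotamidae,Choeropsis liberiensis,pygmy hippopotamus,124,117,0.99,223,unguligrade
Perissodactyla,Equidae,Equus caballus (Kiso horse),Kiso horse,144,125,0.95,400,unguligrade
Perissodactyla,Equidae,Equus caballus (thoroughbred),thoroughbred,157,119,0.79,518,unguligrade
Perissodactyla,Rhinocerotidae,Ceratotherium simum,white rhinoceros,149,141,0.99,3400,unguligrade
Perissodactyla,Rhinocerotidae,Rhinoceros unicornis,Indian rhinoceros,145,146,1.00,2100,unguligrade
Perissodactyla,Tapiridae,Tapirus terrestris,South American tapir,131,102,0.87,200,unguligrade
Carnivora,Canidae,Canis lupus,wolf,130,119,0.98,40,digitigrade
Carnivora,Canidae,Chrysocyon brachyurus,maned wolf,133,124,0.98,24,digitigrade
Carnivora,Felidae,Acinonyx jubatus,cheetah,125,112,0.97,48,digitigrade
Carnivora,Felidae,Felis silvestris catus,cat,112,109,0.99,4.8,digitigrade
Carnivora,Felidae,Panthera tigris,Sumatran tiger,125,114,0.98,125,digitigrade
Carnivora,Felidae,Panthera leo,lion,120,108,0.98,188,digitigrade
Carnivora,Herpestidae,Suricata suricatta,meerkat,108,121,0.98,0.7,digitigrade
Primates,Cercopithecidae,Cercopithecus neglectus,De Brazza's monkey,99,108,0.99,4.5,plantigrade
Primates,Cercopithecidae,Macaca fuscata,Japanese macaque,109,109,1.00,16,plantigrade
Rodentia,Caviidae,Dolichotis patagonum,Patagonian mara,99,111,0.98,8,digitigrade
Rodentia,Caviidae,Galea musteloides,yellow-toothed cavy,75,106,0.86,0.34,plantigrade
Rodentia,Muridae,Meriones unguiculatus,Mongolian gerbil,66,95,0.88,0.06,plantigrade
Scandentia,Tupaiidae,Tupaia glis,common tree shrew,84,107,0.92,0.18,plantigrade
Diprotodontia,Macropodidae,Macropus fuliginosus,western grey kangaroo,96,119,0.92,43.5,pentapedal
Diprotodontia,Macropodidae,Macropus giganteus,eastern grey kangaroo,101,122,0.93,41,pentapedal
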