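species,ln_bm,sin_alpha,theta_obs_deg,theta_est_deg,theta_obs_minus_theta_est,theta_r_obs,theta_obs_minus_theta_r_obs
Meriones unguiculatus,4.1,0.87,66,95,-29,69,-3
Tupaia glis,5.2,0.92,84,107,-23,80,4
Galea musteloides,5.8,0.86,75,106,-31,83,-8
Suricata suricatta,6.6,0.99,108,121,-13,93,15
Cercopithecus neglectus,8.4,0.99,99,108,-9,96,3
Felis silvestris catus,8.5,1.00,112,109,3,96,16
Dolichotis patagonum,9.0,0.98,99,111,-12,100,-1
Macaca fuscata,9.7,1.00,109,111,-2,103,6
Capra hircus,9.9,0.99,130,137,-7,116,14
Chrysocyon brachyurus,10.1,0.99,133,124,9,111,22
Canis lupus,10.5,0.98,130,119,11,111,19
Capricornis crispus,10.6,1.00,127,127,0,115,12
Macropus fuliginosus,10.6,0.92,96,119,-23,111,-15
Macropus giganteus,10.7,0.93,101,122,-21,113,-12
Acinonyx jubatus,10.8,0.97,125,112,13,109,16
Ammotragus lervia,11.1,0.98,142,130,12,118,24
Cervus nippon yesoensis,11.2,1.00,126,123,3,116,10
Panthera tigris,11.7,0.98,125,114,11,114,11
Rangifer tarandus,11.7,1.00,121,122,-1,118,3
Choeropsis liberiensis,12.1,0.99,124,117,7,117,7
Panthera leo,12.2,0.98,120,108,12,113,7
Tapirus terrestris,12.3,0.88,131,103,28,111,20
Equus caballus (Kiso horse),12.9,0.95,144,125,19,125,19
Equus caballus (thoroughbred),13.2,0.79,157,119,38,123,34
Giraffa reticulata,13.8,0.99,146,140,6,136,10
Rhinoceros unicornis,14.6,1.00,145,146,-1,142,3
Ceratotherium simum,15.0,0.99,149,141,8,142,7
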