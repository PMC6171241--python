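carbon_source,dose,response_kind,response,sd,n
control,0.00,biomass,9.58,0.48,3
control,0.00,ara_content,8.95,0.17,3
control,0.00,epa_content,6.40,0.22,3
control,0.00,tfa_content,45.62,2.82,3
control,0.00,ara_concentration,85.7,1.0,3
control,0.00,epa_concentration,61.3,2.1,3
control,0.00,tfa_concentration,437.0,25.8,3
glucose,0.05,biomass,10.54,0.53,3
glucose,0.05,ara_content,9.10,0.02,3
glucose,0.05,epa_content,6.88,0.43,3
glucose,0.05,tfa_content,47.00,3.25,3
glucose,0.05,ara_concentration,95.9,7.6,3
glucose,0.05,epa_concentration,72.5,6.4,3
glucose,0.05,tfa_concentration,495.4,27.5,3
glucose,0.10,biomass,11.32,0.57,3
glucose,0.10,ara_content,8.64,0.83,3
glucose,0.10,epa_content,5.78,0.82,3
glucose,0.10,tfa_content,44.64,2.32,3
glucose,0.10,ara_concentration,97.8,4.9,3
glucose,0.10,epa_concentration,65.4,7.3,3
glucose,0.10,tfa_concentration,505.3,25.7,3
glucose,0.25,biomass,13.17,0.63,3
glucose,0.25,ara_content,8.86,0.23,3
glucose,0.25,epa_content,6.12,0.36,3
glucose,0.25,tfa_content,46.49,3.38,3
glucose,0.25,ara_concentration,116.7,2.1,3
glucose,0.25,epa_concentration,80.6,5.0,3
glucose,0.25,tfa_concentration,612.3,36.0,3
glucose,0.50,biomass,15.36,0.71,3
glucose,0.50,ara_content,9.03,0.57,3
glucose,0.50,epa_content,5.86,0.39,3
glucose,0.50,tfa_content,46.76,2.61,3
glucose,0.50,ara_concentration,138.7,2.1,3
glucose,0.50,epa_concentration,90.0,5.4,3
glucose,0.50,tfa_concentration,718.2,39.5,3
glucose,0.75,biomass,15.04,0.75,3
glucose,0.75,ara_content,8.48,0.15,3
glucose,0.75,epa_content,6.63,0.15,3
glucose,0.75,tfa_content,45.22,2.45,3
glucose,0.75,ara_concentration,127.5,1.9,3
glucose,0.75,epa_concentration,99.7,9.4,3
glucose,0.75,tfa_concentration,680.1,30.0,3
glucose,1.00,biomass,8.45,0.42,3
glucose,1.00,ara_content,8.72,0.15,3
glucose,1.00,epa_content,5.05,0.52,3
glucose,1.00,tfa_content,44.29,3.76,3
glucose,1.00,ara_concentration,73.7,0.1,3
glucose,1.00,epa_concentration,42.7,3.3,3
glucose,1.00,tfa_concentration,374.3,17.8,3
sodium_acetate,0.05,biomass,11.29,0.52,3
sodium_acetate,0.05,ara_content,10.58,1.11,3
sodium_acetate,0.05,epa_content,7.25,0.63,3
sodium_acetate,0.05,tfa_content,49.28,4.64,3
sodium_acetate,0.05,ara_concentration,119.5,18.6,3
sodium_acetate,0.05,epa_concentration,81.9,8.4,3
sodium_acetate,0.05,tfa_concentration,556.4,25.8,3
sodium_acetate,0.10,biomass,12.73,0.57,3
sodium_acetate,0.10,ara_content,11.66,0.53,3
sodium_acetate,0.10,epa_content,7.61,0.83,3
sodium_acetate,0.10,tfa_content,51.84,2.92,3
sodium_acetate,0.10,ara_concentration,148.4,2.0,3
sodium_acetate,0.10,epa_concentration,96.9,6.3,3
sodium_acetate,0.10,tfa_concentration,659.9,36.0,3
sodium_acetate,0.25,biomass,14.05,0.70,3
sodium_acetate,0.25,ara_content,12.85,0.03,3
sodium_acetate,0.25,epa_content,8.62,0.34,3
sodium_acetate,0.25,tfa_content,54.17,2.85,3
sodium_acetate,0.25,ara_concentration,180.5,10.4,3
sodium_acetate,0.25,epa_concentration,121.1,7.4,3
sodium_acetate,0.25,tfa_concentration,761.1,40.1,3
sodium_acetate,0.50,biomass,10.55,0.46,3
sodium_acetate,0.50,ara_content,10.34,0.61,3
sodium_acetate,0.50,epa_content,7.91,0.93,3
sodium_acetate,0.50,tfa_content,45.15,2.75,3
sodium_acetate,0.50,ara_concentration,109.1,10.8,3
sodium_acetate,0.50,epa_concentration,83.5,8.1,3
sodium_acetate,0.50,tfa_concentration,476.3,28.3,3
sodium_acetate,0.75,biomass,6.86,0.37,3
sodium_acetate,0.75,ara_content,8.88,0.61,3
sodium_acetate,0.75,epa_content,6.35,0.75,3
sodium_acetate,0.75,tfa_content,42.13,3.65,3
sodium_acetate,0.75,ara_concentration,60.9,1.3,3
sodium_acetate,0.75,epa_concentration,43.6,4.1,3
sodium_acetate,0.75,tfa_concentration,289.0,15.4,3
sodium_acetate,1.00,biomass,3.54,0.81,3
sodium_acetate,1.00,ara_content,8.24,0.37,3
sodium_acetate,1.00,epa_content,5.57,0.78,3
sodium_acetate,1.00,tfa_content,38.16,1.98,3
sodium_acetate,1.00,ara_concentration,29.2,12.5,3
sodium_acetate,1.00,epa_concentration,19.7,2.9,3
sodium_acetate,1.00,tfa_concentration,135.1,7.6,3
glycerol,0.05,biomass,11.27,0.56,3
glycerol,0.05,ara_content,9.75,0.67,3
glycerol,0.05,epa_content,5.61,0.82,3
glycerol,0.05,tfa_content,50.80,3.54,3
glycerol,0.05,ara_concentration,109.9,8.4,3
glycerol,0.05,epa_concentration,63.2,6.1,3
glycerol,0.05,tfa_concentration,572.5,26.4,3
glycerol,0.10,biomass,12.37,0.62,3
glycerol,0.10,ara_content,10.89,0.92,3
glycerol,0.10,epa_content,4.55,0.27,3
glycerol,0.10,tfa_content,56.00,2.88,3
glycerol,0.10,ara_concentration,134.7,28.1,3
glycerol,0.10,epa_concentration,56.3,2.2,3
glycerol,0.10,tfa_concentration,692.7,36.4,3
glycerol,0.25,biomass,14.38,0.72,3
glycerol,0.25,ara_content,13.43,0.60,3
glycerol,0.25,epa_content,4.37,0.28,3
glycerol,0.25,tfa_content,62.22,4.11,3
glycerol,0.25,ara_concentration,193.1,14.6,3
glycerol,0.25,epa_concentration,62.8,4.9,3
glycerol,0.25,tfa_concentration,894.7,47.3,3
glycerol,0.50,biomass,15.72,0.79,3
glycerol,0.50,ara_content,13.67,0.84,3
glycerol,0.50,epa_content,4.75,0.57,3
glycerol,0.50,tfa_content,63.41,4.17,3
glycerol,0.50,ara_concentration,214.9,26.8,3
glycerol,0.50,epa_concentration,74.7,7.3,3
glycerol,0.50,tfa_concentration,996.8,39.8,3
glycerol,0.75,biomass,9.13,0.46,3
glycerol,0.75,ara_content,9.44,0.98,3
glycerol,0.75,epa_content,3.98,0.91,3
glycerol,0.75,tfa_content,58.56,3.28,3
glycerol,0.75,ara_concentration,86.2,16.9,3
glycerol,0.75,epa_concentration,36.3,2.8,3
glycerol,0.75,tfa_concentration,534.7,27.4,3
glycerol,1.00,biomass,4.00,1.2,3
glycerol,1.00,ara_content,6.45,0.13,3
glycerol,1.00,epa_content,2.66,0.33,3
glycerol,1.00,tfa_content,48.64,3.42,3
glycerol,1.00,ara_concentration,25.8,3.8,3
glycerol,1.00,epa_concentration,10.6,1.5,3
glycerol,1.00,tfa_concentration,194.6,12.7,3
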