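product,dimension,polarity,A,B
mouthwash,breath_hours,higher_better,4.5,7.2
mouthwash,germs_killed_pct,higher_better,77,56
exercise_class,fee_usd,lower_better,9.49,6.49
exercise_class,calories_kcal,higher_better,356,259
chocolate_box,amount_oz,higher_better,26,33
chocolate_box,variety,higher_better,9,5
gps,update_hz,higher_better,3.04,5.62
gps,accuracy_m,lower_better,4.97,7.83
mobile_battery,price_usd,lower_better,19.93,13.49
mobile_battery,talk_time_hours,higher_better,14.55,9.25
light_bulb,life_hours,higher_better,1309,1923
light_bulb,price_usd,lower_better,1.35,2.50
air_purifier,noise_db,lower_better,64.7,39.3
air_purifier,efficiency_cfm,higher_better,325,203
strawberry,quantity_g,higher_better,407,452
strawberry,price_usd,lower_better,2.58,2.85
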