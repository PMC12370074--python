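survey_type,role,rate_per_person_day,persons,days,cost_usd,surveyed_distance_km,surveyed_hours
boat,Surveyor,15,4,21,1292,72,133
boat,Data Supervisor,15,2,7,215,72,133
drone,Drone Pilot,38,1,5,192,694.2,13.3
drone,Drone Assistant,15,1,5,77,694.2,13.3
drone,Image Processing,23,1,7,162,694.2,13.3
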