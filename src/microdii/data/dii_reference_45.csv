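parameter,units,global_mean,global_sd,effect_score
alcohol,g,13.98,3.72,-0.278
vitamin_b12,ug,5.15,2.70,0.106
vitamin_b6,mg,1.47,0.74,-0.365
beta_carotene,ug,3718.0,1720.0,-0.584
caffeine,g,8.05,6.67,-0.110
carbohydrate,g,272.2,40.0,0.097
cholesterol,mg,279.4,51.2,0.110
energy,kcal,2056.0,338.0,0.180
total_fat,g,71.4,19.4,0.298
fiber,g,18.8,4.9,-0.663
folic_acid,ug,273.0,70.7,-0.190
iron,mg,13.35,3.71,0.032
magnesium,mg,310.1,139.4,-0.484
mufa,g,27.0,6.1,-0.009
niacin,mg,25.90,11.77,-0.246
protein,g,79.4,13.9,0.021
pufa,g,13.88,3.76,-0.337
riboflavin,mg,1.70,0.79,-0.068
saturated_fat,g,28.6,8.0,0.373
selenium,ug,67.0,25.1,-0.191
thiamin,mg,1.70,0.66,-0.098
trans_fat,g,3.15,3.75,0.229
vitamin_a,RE,983.9,518.6,-0.401
vitamin_c,mg,118.2,43.46,-0.424
vitamin_d,ug,6.26,2.21,-0.446
vitamin_e,mg,8.73,1.49,-0.419
zinc,mg,9.84,2.19,-0.313
anthocyanidins,mg,18.05,21.14,-0.131
eugenol,mg,0.01,0.08,-0.140
flavan_3_ol,mg,95.8,85.9,-0.415
flavanones,mg,11.7,3.82,-0.250
flavones,mg,1.55,0.07,-0.616
flavonols,mg,17.7,6.79,-0.467
garlic,g,4.35,2.90,-0.412
ginger,g,59.0,63.2,-0.453
green_black_tea,g,1.69,1.53,-0.536
isoflavones,mg,1.20,0.20,-0.593
n3_fatty_acids,g,1.06,1.06,-0.436
n6_fatty_acids,g,10.80,7.50,-0.159
onion,g,35.9,18.4,-0.301
pepper,g,10.0,7.07,-0.131
rosemary,mg,1.00,15.0,-0.013
saffron,g,0.37,1.78,-0.140
thyme_oregano,mg,0.33,0.99,-0.102
turmeric,mg,533.6,754.3,-0.785
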