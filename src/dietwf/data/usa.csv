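category,food_group,classification,serving_g_edible,servings_per_week,g_per_week,green_l_per_kg,blue_l_per_kg,grey_l_per_kg,weekly_green_l,weekly_blue_l,weekly_grey_l,weekly_total_l,note
Green vegetables,vegetables,plant,60,1.5,133,170,60,96,23,6,12,41,
Red and orange vegetables,vegetables,plant,145,5.5,916,201,32,68,184,30,62,276,
Starchy vegetables,vegetables,plant,161,5,944,757,49,113,744,43,97,884,
Other vegetables,vegetables,plant,112,4,563,292,76,206,164,43,116,323,
Dry pulses,pulses,plant,74,1.5,111,3174,218,879,352,24,98,474,
Fruit,fruit,plant,161,14,3175,458,141,92,1372,424,266,2062,
Whole grains,cereals,plant,28,21,588,2059,254,150,1211,149,88,1448,
Refined grains,cereals,plant,28,21,588,1531,351,211,900,206,124,1230,
Dairy,dairy,animal,114.6667,21,2408,3130,321,262,4459,454,373,5284,serving is the mean cup-equivalent mass (244 g milk / 43 g natural / 57 g processed cheese); per-kg column is the simple member mean while the weekly WF is serving-weighted
"Meat, poultry, eggs",meat and eggs,animal,34,26,964,6365,392,492,5550,354,465,6369,per-kg column is the simple member mean; weekly WF is serving-weighted
Seafood,seafood,animal,28,8,320,815,90,83,261,29,27,316,charged mass is the aquaculture share of the recommendation; wild-caught fish carries 0 L/kg
"Nuts, seed, soy products",nuts,plant,19,5,96,5200,2724,1034,426,193,73,692,per-kg column is the simple member mean; weekly WF is serving-weighted
Oils,oils,plant,27,7,189,3603,288,355,681,54,67,802,
Limit on calories for other use (240 kcal/day),indulgence,other,260,7,1823,749,224,152,882,193,161,1238,sugar/jam/alcohol allowance; per-kg column is the simple member mean
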