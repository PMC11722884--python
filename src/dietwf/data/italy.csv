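category,food_group,classification,serving_g_edible,servings_per_week,g_per_week,green_l_per_kg,blue_l_per_kg,grey_l_per_kg,weekly_green_l,weekly_blue_l,weekly_grey_l,weekly_total_l,note
Red meat,meat and eggs,animal,100,1,113,9661,505,537,1092,57,61,1209,
White meat,meat and eggs,animal,100,2,286,3545,313,467,1014,90,134,1237,
Fish/seafood,meat and eggs,animal,150,2,428,815,90,83,349,38,36,422,
Processed fish,meat and eggs,animal,50,1,50,815,90,83,41,4,4,49,
Eggs,meat and eggs,animal,50,3,172.5,2592,244,429,447,42,74,563,
Milk/yoghurt,dairy,animal,125,21,2625,863,86,72,2265,226,189,2678,
Soft cheese,dairy,animal,100,2,200,4264,439,357,853,88,71,1012,
Hard cheese,dairy,animal,50,1,50,4264,439,357,213,22,18,253,
Bread,cereals and potatoes,plant,50,24.5,1225,1124,301,183,1377,369,224,1970,
Bread analogue,cereals and potatoes,plant,80,10.5,840,1562,322,223,1312,270,188,1770,
"Pasta, rice, barley",cereals and potatoes,plant,30,1,30,1126,322,113,34,10,3,48,
Sweet bakery (croissants),cereals and potatoes,plant,50,1,50,2843,812,284,142,41,14,203,
Sweet bakery (biscuits),cereals and potatoes,plant,30,1,30,2140,611,214,64,18,6,92,
Breakfast cereals,cereals and potatoes,plant,30,2,60,1998,245,173,120,15,10,145,
Potatoes,cereals and potatoes,plant,200,2,482,191,33,63,92,16,30,138,
Dry pulses,pulses,plant,50,3,150,3174,218,879,476,33,132,641,
Vegetable oil,fats,plant,10,14,140,7994,1324,313,1119,185,44,1348,
Butter,fats,plant,10,7,70,4965,465,393,348,33,28,389,
Fresh fruit,fruit and vegetables,plant,150,21,4074,540,171,108,2200,695,441,3337,
Nuts (shelled),fruit and vegetables,plant,30,2,60,5761,3253,1231,346,195,74,615,
Leafy vegetables,fruit and vegetables,plant,200,10.5,2919,239,69,94,698,201,274,1173,
Other vegetables,fruit and vegetables,plant,80,7,742,147,21,104,109,16,77,201,
Sugar,indulgence,other,5,10.5,52.5,860,327,137,45,17,7,70,
Jam,indulgence,other,20,2,40,1277,416,321,51,17,13,81,per-kg value carried verbatim; not reproducible from the 35% fruit / 40% sugar rule with any tabulated fruit or sugar WF
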