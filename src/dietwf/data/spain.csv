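category,food_group,classification,serving_g_edible,servings_per_week,g_per_week,green_l_per_kg,blue_l_per_kg,grey_l_per_kg,weekly_green_l,weekly_blue_l,weekly_grey_l,weekly_total_l,note
Cereals and potatoes,cereals and potatoes,plant,79,27,2336,1204,252,166,2118,458,325,2902,
Fruit,fruit,plant,175,19,4350,412,112,95,1793,486,412,2691,
Vegetables,vegetables,plant,200,13,3061,189,38,103,579,118,316,1003,
Extra Virgin Olive Oil,oils,plant,13.7368,19,261,11826,2388,217,3089,624,57,3769,serving back-computed from g/week (published 14 g x 19 = 266 g exceeds the published 261 g/week; the energy rescale rounds the printed serving)
Dairy,dairy,animal,125,13,1664,2564,263,215,4829,493,404,5724,per-kg column is the simple member mean (milk and cheeses); weekly WF is serving-weighted
Seafood,seafood,animal,125,3,476,815,90,83,387,43,39,469,
White meat,meat and eggs,animal,125,2,317,3545,313,467,1124,99,148,1371,
Red meat,meat and eggs,animal,125,0.4,53,14414,550,451,762,29,24,815,
Eggs,meat and eggs,animal,58,3,255,503,47,83,503,47,83,634,published per-kg cells equal the weekly cells and are inconsistent with the row's mass arithmetic; weekly value carried as published
Dry pulses,pulses,plant,70,2,160,3174,218,879,508,35,141,683,
Nuts,nuts,plant,23.75,4,95,5761,3253,1231,548,310,117,975,serving back-computed from g/week (published 25 g x 4 = 100 g exceeds the published 95 g/week)
Sugar,indulgence,other,5,10.5,52.5,858,327,137,45,17,7,69,published g/week cell (1668) is inconsistent with serving math and the weekly WF; 52.5 g used
Jam,indulgence,other,20,2,40,1277,416,321,51,17,13,81,per-kg value carried verbatim (see Italy note)
Wine/beer,indulgence,other,150,10.5,1575,431,77,76,585,89,93,769,
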