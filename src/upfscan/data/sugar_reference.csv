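subgroup,added_sugars_g_per_100
Sweet cookies,25
Cakes and sweet pies,30
Chocolate,45
Sweets in general,40
Carbonated beverages,10
Other sugary drinks,9
Dairy beverages,12
Ice cream,22
Breakfast cereals,20
Sauces and spreads,8
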