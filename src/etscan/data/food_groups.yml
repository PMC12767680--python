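# Harmonization of raw source food-group vocabularies onto the 16-group
# taxonomy used throughout the package. Keys are case-folded raw group
# labels from the two source schemas (db_A carries Norwegian labels, db_B
# English retail labels); values are canonical group names. Raw labels not
# listed here fall back to "Others".
iskrem: Desserts & Ice Creams
desserter: Desserts & Ice Creams
dessert og iskrem: Desserts & Ice Creams
desserts: Desserts & Ice Creams
ice cream: Desserts & Ice Creams
frozen desserts: Desserts & Ice Creams
drikkevarer: Beverages
drikke: Beverages
drinks: Beverages
soft drinks: Beverages
juice: Beverages
fisk og skalldyr: Fish & Shellfish
sjømat: Fish & Shellfish
seafood: Fish & Shellfish
fish: Fish & Shellfish
kjøtt og fjærkre: Meat & Poultry
kjøttprodukter: Meat & Poultry
meat: Meat & Poultry
poultry: Meat & Poultry
cold cuts: Meat & Poultry
fett og margarin: Fats, Margarine & Spreads
smør og margarin: Fats, Margarine & Spreads
spreads: Fats, Margarine & Spreads
margarine: Fats, Margarine & Spreads
ferdigmat: Premade Food & Dinner Kits
middagsretter: Premade Food & Dinner Kits
ready meals: Premade Food & Dinner Kits
dinner kits: Premade Food & Dinner Kits
snacks: Snacks, Chocolate & Sweets
sjokolade: Snacks, Chocolate & Sweets
godteri: Snacks, Chocolate & Sweets
chocolate: Snacks, Chocolate & Sweets
sweets: Snacks, Chocolate & Sweets
bakervarer: Bakery, Cakes & Pastries
kaker: Bakery, Cakes & Pastries
bread and bakery: Bakery, Cakes & Pastries
pastries: Bakery, Cakes & Pastries
egg og meieri: Eggs & Dairy Products
meieriprodukter: Eggs & Dairy Products
dairy: Eggs & Dairy Products
eggs: Eggs & Dairy Products
korn og frokostblandinger: Grains, Baking Mixes & Cereals
bakemikser: Grains, Baking Mixes & Cereals
cereals: Grains, Baking Mixes & Cereals
grains: Grains, Baking Mixes & Cereals
bakeingredienser: Baking Condiments
baking supplies: Baking Condiments
sauser og dressinger: Sauces, Dressings & Other Dinner Condiments
sauces: Sauces, Dressings & Other Dinner Condiments
dressings: Sauces, Dressings & Other Dinner Condiments
condiments: Sauces, Dressings & Other Dinner Condiments
bearbeidet frukt og grønt: Processed Fruits & Vegetables
syltetøy: Processed Fruits & Vegetables
processed fruit: Processed Fruits & Vegetables
canned vegetables: Processed Fruits & Vegetables
frukt og grønt: Fruit, Vegetables & Legumes
grønnsaker: Fruit, Vegetables & Legumes
fresh produce: Fruit, Vegetables & Legumes
legumes: Fruit, Vegetables & Legumes
barnemat: Infant Food
baby food: Infant Food
infant formula: Infant Food
annet: Others
other: Others
miscellaneous: Others
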