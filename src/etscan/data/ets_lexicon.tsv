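code	canonical_name	synonyms	misspellings	extra_patterns	lump_group	fate
E400	alginic acid	alginsyre			E40x	non_absorbed
E401	sodium alginate	natriumalginat			E40x	non_absorbed
E402	potassium alginate	kaliumalginat			E40x	non_absorbed
E403	ammonium alginate	ammoniumalginat			E40x	non_absorbed
E404	calcium alginate	kalsiumalginat			E40x	non_absorbed
E405	propane-1,2-diol alginate	propylene glycol alginate|propylenglykolalginat			self	non_absorbed
E406	agar	agar-agar	agaragar		self	non_absorbed
E407	carrageenan	karragenan	karagenan|carragenan	(c|k)ar*age*nan	self	non_absorbed
E410	locust bean gum	johannesbrødkjernemel|carob bean gum|carob gum	johannesbrodkjernemel		self	non_absorbed
E412	guar gum	guarkjernemel|guargummi	guargum|guar gumm		self	non_absorbed
E413	tragacanth	tragant|dragant			self	non_absorbed
E414	gum arabic	acacia gum|gummi arabicum|akasiegummi	gum arabicum		self	non_absorbed
E415	xanthan gum	xantangummi|ksantangummi	xantan gum|xanthangum		self	non_absorbed
E416	karaya gum	karayagummi			self	non_absorbed
E417	tara gum	tarakjernemel|taragummi			self	non_absorbed
E418	gellan gum	gellangummi	gellan gumm		self	non_absorbed
E420	sorbitol	sorbitolsirup|sorbitol syrup	sorbitole		E42x	absorbed
E421	mannitol	mannitt			E42x	absorbed
E422	glycerol	glyserol|glycerine|glycerin			E42x	absorbed
E425	konjac	konjak|konjac gum|konjac glucomannan			self	non_absorbed
E426	soybean hemicellulose	soyahemicellulose			self	non_absorbed
E427	cassia gum	cassiagummi			self	non_absorbed
E431	polyoxyethylene (40) stearate	polyoksyetylenstearat			self	absorbed
E432	polysorbate 20	polysorbat 20			self	absorbed
E433	polysorbate 80	polysorbat 80	polysorbat80		self	absorbed
E434	polysorbate 40	polysorbat 40			self	absorbed
E435	polysorbate 60	polysorbat 60			self	absorbed
E436	polysorbate 65	polysorbat 65			self	absorbed
E440	pectin	pektin|pectins|amidated pectin|amidert pektin	pectine|pektine		self	non_absorbed
E442	ammonium phosphatides	ammoniumfosfatider			self	absorbed
E450	diphosphates	difosfater|difosfat|diphosphate	diphospate		E45x	absorbed
E451	triphosphates	trifosfater|trifosfat|triphosphate			E45x	absorbed
E452	polyphosphates	polyfosfater|polyfosfat|polyphosphate			E45x	absorbed
E456	potassium polyaspartate	kaliumpolyaspartat			self	absorbed
E459	beta-cyclodextrin	betacyklodekstrin|beta-cyklodekstrin			self	absorbed
E460	cellulose	mikrokrystallinsk cellulose|microcrystalline cellulose|cellulose powder			self	non_absorbed
E461	methyl cellulose	methylcellulose|metylcellulose			self	non_absorbed
E463	hydroxypropyl cellulose	hydroksypropylcellulose			self	non_absorbed
E464	hydroxypropyl methyl cellulose	hypromellose|hydroksypropylmetylcellulose			self	non_absorbed
E465	ethyl methyl cellulose	etylmetylcellulose|methyl ethyl cellulose			self	non_absorbed
E466	carboxymethyl cellulose	carboxymethylcellulose|karboksymetylcellulose|cellulose gum|cellulosegummi	carboxymetyl cellulose		self	non_absorbed
E470	salts of fatty acids	fettsyresalter|magnesium salts of fatty acids			E47x	absorbed
E471	mono- and diglycerides of fatty acids	monoglycerides|diglycerides|mono- og diglyserider av fettsyrer|monoglyserider|diglyserider	mono og diglyserider		E47x	absorbed
E472	esters of mono- and diglycerides of fatty acids	acetic acid esters of mono- and diglycerides of fatty acids|lactic acid esters of mono- and diglycerides of fatty acids|citric acid esters of mono- and diglycerides of fatty acids|eddiksyreestere av mono- og diglyserider|sitronsyreestere av mono- og diglyserider			E47x	absorbed
E473	sucrose esters of fatty acids	sukroseestere av fettsyrer|sucrose esters			E47x	absorbed
E474	sucroglycerides	sukroglyserider			E47x	absorbed
E475	polyglycerol esters of fatty acids	polyglyserolestere av fettsyrer			E47x	absorbed
E476	polyglycerol polyricinoleate	polyglyserolpolyrisinoleat|pgpr			E47x	absorbed
E477	propane-1,2-diol esters of fatty acids	propylenglykolestere av fettsyrer			E47x	absorbed
E479b	thermally oxidized soybean oil	termisk oksidert soyaolje			self	absorbed
E481	sodium stearoyl-2-lactylate	natriumstearoyllaktylat|sodium stearoyl lactylate			self	absorbed
E482	calcium stearoyl-2-lactylate	kalsiumstearoyllaktylat|calcium stearoyl lactylate			self	absorbed
E483	stearyl tartrate	stearyltartrat			self	absorbed
E491	sorbitan monostearate	sorbitanmonostearat			self	absorbed
E492	sorbitan tristearate	sorbitantristearat			self	absorbed
E493	sorbitan monolaurate	sorbitanmonolaurat			self	absorbed
E494	sorbitan monooleate	sorbitanmonooleat			self	absorbed
E495	sorbitan monopalmitate	sorbitanmonopalmitat			self	absorbed
E499	stigmasterol-rich plant sterols	stigmasterolrike plantesteroler			self	absorbed
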