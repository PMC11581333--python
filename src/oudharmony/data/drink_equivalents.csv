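token,beverage,drinks_per_unit
beer,beer,1.0
beers,beer,1.0
brew,beer,1.0
lager,beer,1.0
ale,beer,1.0
malt liquor,beer,1.0
wine,wine,1.0
glass of wine,wine,1.0
glasses of wine,wine,1.0
champagne,wine,1.0
shot,spirits,1.0
shots,spirits,1.0
rum,spirits,1.0
vodka,spirits,1.0
whiskey,spirits,1.0
whisky,spirits,1.0
gin,spirits,1.0
tequila,spirits,1.0
brandy,spirits,1.0
schnapps,spirits,1.0
liquor,spirits,1.0
mixed drink,spirits,1.0
mixed drinks,spirits,1.0
cocktail,spirits,1.0
cocktails,spirits,1.0
margarita,spirits,1.0
margaritas,spirits,1.0
drink,generic,1.0
drinks,generic,1.0
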