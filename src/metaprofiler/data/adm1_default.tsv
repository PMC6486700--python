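step_id	stage	substrate	ec	ko	restriction
hydrolysis_carbohydrate	hydrolysis	carbohydrate	3.2.1.4;3.2.1.1;3.2.1.21	K01179	none
hydrolysis_protein	hydrolysis	protein	3.4.21.62;3.4.24.28	K01362	none
hydrolysis_lipid	hydrolysis	lipid	3.1.1.3	K01046	none
uptake_sugar	substrate_uptake	carbohydrate		K02027;K10111	none
uptake_amino_acid	substrate_uptake	protein		K01999	none
fermentation_sugar	acidogenesis/fermentation	carbohydrate	2.7.1.11;1.2.7.1		bacteria_only
fermentation_alcohol	acidogenesis/fermentation	alcohol	1.1.1.1		bacteria_only
fermentation_lactate	acidogenesis/fermentation	lactate	1.1.1.27		bacteria_only
fermentation_amino_acid	acidogenesis/fermentation	protein	4.3.1.19	K01754	bacteria_only
acetogenesis_butyrate	acetogenesis	butyrate	2.8.3.8	K00248	bacteria_only
acetogenesis_propionate	acetogenesis	propionate		K01026	bacteria_only
acetogenesis_valerate	acetogenesis	valerate		K00252	bacteria_only
methanogenesis_hydrogenotrophic	methanogenesis	H2/CO2		K00200;K00201;K00672;K01499;K00320;K00577;K00399;K00401;K00402	archaea_only
methanogenesis_acetoclastic	methanogenesis	acetate		K00925;K00625;K00193;K00194;K00197	archaea_only
methanogenesis_methyl	methanogenesis	methyl		K04480;K14080	archaea_only
one_carbon_bacterial	one_carbon	acetate		K00198;K15023;K00193;K00194;K00197	bacteria_only
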