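scientific_name	family	common_names	iucn_status
Thunnus alalunga	Scombridae	Albacore	near_threatened
Thunnus thynnus	Scombridae	Atlantic Bluefin tuna	endangered
Thunnus orientalis	Scombridae	Pacific Bluefin tuna	vulnerable
Thunnus albacares	Scombridae	Yellowfin tuna	near_threatened
Thunnus obesus	Scombridae	Bigeye tuna	vulnerable
Thunnus atlanticus	Scombridae	Blackfin tuna	least_concern
Thunnus maccoyii	Scombridae	Southern Bluefin tuna	critically_endangered
Thunnus tonggol	Scombridae	Longtail tuna	data_deficient
Seriola lalandi	Carangidae	Yellowtail amberjack	not_assessed
Seriola quinqueradiata	Carangidae	Japanese amberjack	not_assessed
Seriola zonata	Carangidae	Banded rudderfish	least_concern
Anguilla anguilla	Anguillidae	European eel	critically_endangered
Anguilla rostrata	Anguillidae	American eel	endangered
Anguilla japonica	Anguillidae	Japanese eel	endangered
Anguilla marmorata	Anguillidae	Giant mottled eel	least_concern
Dicentrarchus labrax	Moronidae	European seabass	least_concern
Lateolabrax japonicus	Lateolabracidae	Japanese seabass	not_assessed
Lateolabrax maculatus	Lateolabracidae	Spotted seabass	not_assessed
Scomber scombrus	Scombridae	Mackerel|Atlantic mackerel	least_concern
Sparus aurata	Sparidae	Gilthead bream	least_concern
Makaira nigricans	Istiophoridae	Blue marlin	data_deficient
Xiphias gladius	Xiphiidae	Swordfish	least_concern
Lates calcarifer	Latidae	Barramundi	not_assessed
Anoplopoma fimbria	Anoplopomatidae	Sablefish|Black cod	not_assessed
Clupea harengus	Clupeidae	Herring|Atlantic herring	least_concern
Scomberomorus commerson	Scombridae	Narrow-barred Spanish mackerel	near_threatened
Scomberomorus maculatus	Scombridae	Atlantic Spanish mackerel	least_concern
Scomberomorus cavalla	Scombridae	King mackerel	least_concern
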